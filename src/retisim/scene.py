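"""Light sources and imaging targets.

Spectral sampling plans built from the D65 daylight illuminant, the
Lambertian pinhole source, a three-bar resolution chart generator with
angular calibration, and the photopic/mesopic scene polarity handling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._cie_data import CIE_WAVELENGTHS_NM, D65_SPD
from .optics_core import VISIBLE_RANGE, RayBundle

__all__ = [
    "SpectralSamplingPlan",
    "SceneTarget",
    "vergence",
    "angular_subtense",
    "sample_pinhole_rays",
    "generate_usaf_chart",
    "chart_to_radiance",
    "usaf_frequency_lp_per_mm",
    "DEFAULT_CALIBRATION_MM_PER_DEG",
    "DARK_REFLECTANCE",
    "LIGHT_REFLECTANCE",
]

ARCMIN_PER_RAD = 60.0 * 180.0 / math.pi

#: print reflectance levels used for chart foreground/background
DARK_REFLECTANCE = 0.04
LIGHT_REFLECTANCE = 0.95


# ---------------------------------------------------------------------------
# Spectral sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralSamplingPlan:
    """Wavelength bins with illuminant-derived relative power weights.

    ``centers``/``edges`` in micrometres; ``weights`` sum to 1 and are
    proportional to the illuminant power integrated over each bin.
    """

    centers: np.ndarray
    edges: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers", np.asarray(self.centers, dtype=float))
        object.__setattr__(self, "edges", np.asarray(self.edges, dtype=float))
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("bin weights must be non-negative")
        object.__setattr__(self, "weights", w / w.sum())

    @property
    def n_bins(self) -> int:
        return self.centers.size

    @classmethod
    def d65(cls, n_bins: int = 40,
            wavelength_range: tuple = VISIBLE_RANGE) -> "SpectralSamplingPlan":
        """Bin the tabulated D65 spectral power distribution.

        Default: 40 bins of 10 nm covering 0.38-0.78 um. The 5 nm D65
        table is integrated (trapezoid rule on a 1 nm grid) per bin.
        """
        lo, hi = wavelength_range
        edges = np.linspace(lo, hi, n_bins + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        tab_wl = np.asarray(CIE_WAVELENGTHS_NM) * 1e-3
        tab_p = np.asarray(D65_SPD)
        weights = np.empty(n_bins)
        for i in range(n_bins):
            grid = np.linspace(edges[i], edges[i + 1], 11)
            weights[i] = np.trapezoid(np.interp(grid, tab_wl, tab_p), grid)
        return cls(centers=centers, edges=edges, weights=weights)

    def mean_wavelength(self) -> float:
        return float(np.sum(self.centers * self.weights))


# ---------------------------------------------------------------------------
# Geometry utilities
# ---------------------------------------------------------------------------

def vergence(distance_m: float) -> float:
    """Object vergence in diopters: reciprocal distance in metres."""
    if not distance_m > 0:
        raise ValueError("distance must be positive")
    return 1.0 / distance_m


def angular_subtense(size_m: float, distance_m: float) -> float:
    """Full angular subtense (arcmin) of an object of the given size."""
    if not (size_m > 0 and distance_m > 0):
        raise ValueError("size and distance must be positive")
    return 2.0 * math.atan(0.5 * size_m / distance_m) * ARCMIN_PER_RAD


# ---------------------------------------------------------------------------
# Pinhole source
# ---------------------------------------------------------------------------

def sample_pinhole_rays(n: int, subtense_arcmin: float, vergence_d: float,
                        plan: SpectralSamplingPlan, pupil_mm: float,
                        rng: np.random.Generator,
                        pupil_z_mm: float = 3.52,
                        pupil_margin: float = 1.15,
                        importance: bool = True,
                        far_distance_m: float = 100.0) -> RayBundle:
    """Monte-Carlo rays from a circular Lambertian disc source.

    Origins are uniform over the source disc at the object distance
    (``1/vergence_d``, or ``far_distance_m`` at zero vergence); emission
    wavelengths are drawn from the plan's illuminant weights. With
    ``importance=True`` directions are drawn toward a disc slightly
    larger than the pupil and weights carry the exact Lambertian
    solid-angle factor ``cos(theta_e) cos(theta_t) A / (pi d^2)``; with
    ``importance=False`` directions are naive cosine-weighted hemisphere
    samples with unit weight (reference estimator for tests).
    """
    if n < 1:
        raise ValueError("need at least one ray")
    if not pupil_mm > 0:
        raise ValueError("zero pupil")
    s_mm = 1000.0 / vergence_d if vergence_d > 1e-9 else far_distance_m * 1000.0
    r_src = s_mm * math.tan(0.5 * subtense_arcmin / ARCMIN_PER_RAD)
    u = rng.random(n)
    phi = rng.random(n) * 2.0 * math.pi
    rs = r_src * np.sqrt(u)
    origin = np.column_stack([rs * np.cos(phi), rs * np.sin(phi),
                              np.full(n, -s_mm)])
    if importance:
        a_t = 0.5 * pupil_mm * pupil_margin
        ut = rng.random(n)
        phit = rng.random(n) * 2.0 * math.pi
        rt = a_t * np.sqrt(ut)
        target = np.column_stack([rt * np.cos(phit), rt * np.sin(phit),
                                  np.full(n, pupil_z_mm)])
        d = target - origin
        dist = np.linalg.norm(d, axis=1)
        d /= dist[:, None]
        cos_e = d[:, 2]           # source normal along +z
        cos_t = d[:, 2]           # target disc also axis-normal
        area = math.pi * a_t**2
        weight = cos_e * cos_t * area / (math.pi * dist**2)
    else:
        # cosine-weighted hemisphere around +z
        ud = rng.random(n)
        phid = rng.random(n) * 2.0 * math.pi
        sin_t = np.sqrt(ud)
        cos_t = np.sqrt(1.0 - ud)
        d = np.column_stack([sin_t * np.cos(phid), sin_t * np.sin(phid), cos_t])
        weight = np.ones(n)
    idx = rng.choice(plan.n_bins, size=n, p=plan.weights)
    wl = plan.centers[idx]
    return RayBundle(origin, d, wl, weight, np.ones(n, bool))


# ---------------------------------------------------------------------------
# USAF-1951 three-bar chart
# ---------------------------------------------------------------------------

def usaf_frequency_lp_per_mm(group: int, element: int) -> float:
    """On-chart spatial frequency 2^(group + (element-1)/6), lp/mm."""
    return 2.0 ** (group + (element - 1) / 6.0)


#: anchor: group -2 element 2 corresponds to 10 cycles/deg at the eye
DEFAULT_CALIBRATION_MM_PER_DEG = 10.0 / usaf_frequency_lp_per_mm(-2, 2)


@dataclass
class SceneTarget:
    """Binary raster target with angular calibration.

    ``raster`` is True on foreground (bar/structure) pixels. ``polarity``
    is ``"photopic"`` (dark structures on a light background) or
    ``"mesopic"`` (light on dark).
    """

    raster: np.ndarray
    pixel_pitch_arcmin: float
    fov_deg: float
    polarity: str = "photopic"
    distance_m: float = math.inf
    metadata: dict = field(default_factory=dict)

    @property
    def vergence_d(self) -> float:
        return 0.0 if math.isinf(self.distance_m) else 1.0 / self.distance_m


def _fill_rect(raster, mm_per_px, extent_mm, x0, y0, w, h):
    """Rasterise an axis-aligned rectangle given in chart mm coordinates
    with origin at the chart centre."""
    npx = raster.shape[0]
    half = extent_mm / 2.0
    i0 = int(round((y0 + half) / mm_per_px))
    i1 = int(round((y0 + h + half) / mm_per_px))
    j0 = int(round((x0 + half) / mm_per_px))
    j1 = int(round((x0 + w + half) / mm_per_px))
    i0, i1 = max(i0, 0), min(i1, npx)
    j0, j1 = max(j0, 0), min(j1, npx)
    if i1 > i0 and j1 > j0:
        raster[i0:i1, j0:j1] = True


def _element_blocks(group: int, element: int):
    """Bar rectangles of one element, in local coords (origin at the
    element's lower-left): three vertical bars then three horizontal."""
    f = usaf_frequency_lp_per_mm(group, element)
    w = 1.0 / (2.0 * f)     # bar width, mm
    L = 5.0 * w             # bar length
    rects = []
    for i in range(3):
        rects.append((i * 2.0 * w, 0.0, w, L))          # vertical bars
    x_h = L + 2.0 * w
    for i in range(3):
        rects.append((x_h, i * 2.0 * w, L, w))          # horizontal bars
    width = x_h + L
    height = L
    return rects, width, height


def generate_usaf_chart(fov_deg: float = 2.0,
                        calibration_mm_per_deg: float = DEFAULT_CALIBRATION_MM_PER_DEG,
                        polarity: str = "photopic",
                        n_pixels: int = 512,
                        groups=(-2, -1, 0, 1),
                        distance_m: float = math.inf) -> SceneTarget:
    """Simplified USAF-1951 style three-bar chart.

    Groups are laid out as side-by-side columns of elements 1-6 (a
    modified flat arrangement rather than the nested spiral of the
    printed chart). The default calibration anchors group -2 element 2 at
    10 cycles/deg; each element's angular frequency is its on-chart
    frequency times the calibration.
    """
    if not fov_deg > 0:
        raise ValueError("field of view must be positive")
    if not calibration_mm_per_deg > 0:
        raise ValueError("calibration must be positive")
    extent_mm = fov_deg * calibration_mm_per_deg
    mm_per_px = extent_mm / n_pixels
    raster = np.zeros((n_pixels, n_pixels), dtype=bool)
    # column layout: widest group first, left to right
    gap = 0.04 * extent_mm
    x_cursor = -0.46 * extent_mm
    elements = {}
    for g in sorted(groups):
        col_width = 0.0
        y_cursor = -0.46 * extent_mm
        for e in range(1, 7):
            rects, w_el, h_el = _element_blocks(g, e)
            for (rx, ry, rw, rh) in rects:
                _fill_rect(raster, mm_per_px, extent_mm,
                           x_cursor + rx, y_cursor + ry, rw, rh)
            elements[f"{g}/{e}"] = (x_cursor, y_cursor, w_el, h_el)
            col_width = max(col_width, w_el)
            y_cursor += h_el + 0.3 * h_el
        x_cursor += col_width + gap
    pitch_arcmin = fov_deg * 60.0 / n_pixels
    meta = {
        "calibration_mm_per_deg": calibration_mm_per_deg,
        "anchor": "group -2 element 2 = 10 cycles/deg",
        "extent_mm": extent_mm,
        "groups": list(groups),
        "elements_mm": elements,
    }
    return SceneTarget(raster=raster, pixel_pitch_arcmin=pitch_arcmin,
                       fov_deg=fov_deg, polarity=polarity,
                       distance_m=distance_m, metadata=meta)


def chart_angular_frequency(target: SceneTarget, group: int, element: int) -> float:
    """Angular frequency (cycles/deg) of an element on a generated chart."""
    return usaf_frequency_lp_per_mm(group, element) * \
        target.metadata["calibration_mm_per_deg"]


def element_pixel_box(target: SceneTarget, group: int, element: int,
                      pad_mm: float = 0.5):
    """Pixel bounding box (i0, i1, j0, j1) of one chart element."""
    x0, y0, w, h = target.metadata["elements_mm"][f"{group}/{element}"]
    extent = target.metadata["extent_mm"]
    npx = target.raster.shape[0]
    mm_per_px = extent / npx
    half = extent / 2.0
    i0 = max(int((y0 - pad_mm + half) / mm_per_px), 0)
    i1 = min(int((y0 + h + pad_mm + half) / mm_per_px) + 1, npx)
    j0 = max(int((x0 - pad_mm + half) / mm_per_px), 0)
    j1 = min(int((x0 + w + pad_mm + half) / mm_per_px) + 1, npx)
    return i0, i1, j0, j1


def export_target(target: SceneTarget, path) -> None:
    """Write the raster as 16-bit grayscale TIFF plus a JSON sidecar."""
    import json
    from pathlib import Path

    import tifffile

    path = Path(path)
    tifffile.imwrite(path, (target.raster.astype(np.uint16) * 65535))
    sidecar = {
        "fov_deg": target.fov_deg,
        "pixel_pitch_arcmin": target.pixel_pitch_arcmin,
        "polarity": target.polarity,
        "vergence_d": target.vergence_d,
        **target.metadata,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Radiance assignment
# ---------------------------------------------------------------------------

def chart_to_radiance(target: SceneTarget, plan: SpectralSamplingPlan,
                      dark: float = DARK_REFLECTANCE,
                      light: float = LIGHT_REFLECTANCE,
                      light_level: float = 1.0) -> np.ndarray:
    """Spectral radiance raster (H, W, n_bins).

    Foreground and background are assigned illuminant-shaped spectra
    scaled by the dark/light reflectance levels; mesopic polarity swaps
    the assignment (light structures on a dark background).
    """
    if target.polarity not in ("photopic", "mesopic"):
        raise ValueError(f"unknown polarity {target.polarity!r}")
    if target.polarity == "photopic":
        fg, bg = dark, light
    else:
        fg, bg = light, dark
    refl = np.where(target.raster, fg, bg).astype(float)
    return light_level * refl[:, :, None] * plan.weights[None, None, :]
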