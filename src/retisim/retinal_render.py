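"""Retinal detector accumulation and colorimetric rendering.

Accumulates traced rays into a spectral radiant-exposure image and
renders it through CIE XYZ to display representations: sRGB with the
absolute colorimetric intent (per-channel clipping), sRGB with the
perceptual intent (a single global chroma scale found by bisection in
the Oklab lightness/chroma/hue representation, preserving per-pixel hue
and lightness), and lightness-only grayscale images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from ._cie_data import CIE_WAVELENGTHS_NM, CMF_XYZ_1931_2DEG
from .optics_core import RayBundle

__all__ = [
    "DetectorConfig",
    "SpectralImage",
    "ColorImage",
    "accumulate_detector",
    "spectral_to_xyz",
    "normalize_exposure_scale",
    "xyz_to_srgb_absolute",
    "xyz_to_srgb_perceptual",
    "lightness_image",
    "cie_lightness",
    "srgb_encode",
    "XYZ_TO_LINEAR_SRGB",
]

_CMF_WL_UM = np.asarray(CIE_WAVELENGTHS_NM) * 1e-3
_CMF = np.asarray(CMF_XYZ_1931_2DEG)

# IEC 61966-2-1 sRGB primaries, D65 white
XYZ_TO_LINEAR_SRGB = np.array([
    [3.2404542, -1.5371385, -0.4985314],
    [-0.9692660, 1.8760108, 0.0415560],
    [0.0556434, -0.2040259, 1.0572252],
])

# Oklab transform (Ottosson 2020)
_OKLAB_M1 = np.array([
    [0.8189330101, 0.3618667424, -0.1288597137],
    [0.0329845436, 0.9293118715, 0.0361456387],
    [0.0482003018, 0.2643662691, 0.6338517070],
])
_OKLAB_M2 = np.array([
    [0.2104542553, 0.7936177850, -0.0040720468],
    [1.9779984951, -2.4285922050, 0.4505937099],
    [0.0259040371, 0.7827717662, -0.8086757660],
])


# ---------------------------------------------------------------------------
# Detector
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectorConfig:
    """Square pixel grid centred on the optical axis at the retina plane."""

    n_pixels: int = 512
    span_mm: float = 1.2
    mm_per_deg: float = 0.29

    def __post_init__(self) -> None:
        if self.n_pixels < 1 or not self.span_mm > 0:
            raise ValueError("zero-sized detector")

    @property
    def pitch_mm(self) -> float:
        return self.span_mm / self.n_pixels

    @property
    def pitch_arcmin(self) -> float:
        return self.pitch_mm / self.mm_per_deg * 60.0


@dataclass
class SpectralImage:
    """Per-pixel, per-wavelength-bin relative radiant exposure."""

    data: np.ndarray            # (H, W, n_bins), >= 0
    bin_centers: np.ndarray     # um
    pitch_mm: float
    pitch_arcmin: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.data < 0):
            raise ValueError("radiant exposure must be non-negative")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape


@dataclass
class ColorImage:
    """Display-referred image in [0, 1] with its rendering-intent tag."""

    data: np.ndarray            # (H, W, 3)
    space: str                  # sRGB-absolute | sRGB-perceptual | lightness
    chroma_scale: float = 1.0
    clip_fraction: float = 0.0
    metadata: dict = field(default_factory=dict)


def accumulate_detector(bundle: RayBundle, detector: DetectorConfig,
                        bin_centers, bin_edges=None) -> SpectralImage:
    """Bin surviving rays into (pixel, wavelength-bin) cells.

    Rays landing outside the detector are counted in the metadata but
    discarded. Ray weights are added to the cell they fall in.
    """
    bin_centers = np.asarray(bin_centers, dtype=float)
    nb = bin_centers.size
    if bin_edges is None:
        mids = 0.5 * (bin_centers[:-1] + bin_centers[1:])
        first = bin_centers[0] - (mids[0] - bin_centers[0])
        last = bin_centers[-1] + (bin_centers[-1] - mids[-1])
        bin_edges = np.concatenate([[first], mids, [last]])
    alive = bundle.alive
    x = bundle.origin[alive, 0]
    y = bundle.origin[alive, 1]
    w = bundle.weight[alive]
    wl = bundle.wavelength[alive]
    half = detector.span_mm / 2.0
    n = detector.n_pixels
    ix = np.floor((x + half) / detector.pitch_mm).astype(int)
    iy = np.floor((y + half) / detector.pitch_mm).astype(int)
    ib = np.clip(np.searchsorted(bin_edges, wl) - 1, 0, nb - 1)
    on = (ix >= 0) & (ix < n) & (iy >= 0) & (iy < n)
    data = np.zeros((n, n, nb))
    np.add.at(data, (iy[on], ix[on], ib[on]), w[on])
    meta = {
        "total_weight": float(bundle.weight[alive].sum()),
        "on_detector_weight": float(w[on].sum()),
        "off_detector_weight": float(w[~on].sum()),
        "n_alive": int(alive.sum()),
        "n_off_detector": int((~on).sum()),
    }
    return SpectralImage(data=data, bin_centers=bin_centers,
                         pitch_mm=detector.pitch_mm,
                         pitch_arcmin=detector.pitch_arcmin, metadata=meta)


# ---------------------------------------------------------------------------
# Colorimetry
# ---------------------------------------------------------------------------

def spectral_to_xyz(img: SpectralImage) -> np.ndarray:
    """Integrate spectral exposure against the CIE 1931 2-deg observer.

    Linear in the input; returns an (H, W, 3) XYZ image in relative
    units.
    """
    wl = img.bin_centers
    lo, hi = _CMF_WL_UM[0], _CMF_WL_UM[-1]
    if np.any(wl < lo - 1e-9) or np.any(wl > hi + 1e-9):
        raise ValueError("bin centers outside the observer-function domain")
    cmf = np.column_stack([np.interp(wl, _CMF_WL_UM, _CMF[:, i]) for i in range(3)])
    return np.einsum("hwb,bc->hwc", img.data, cmf)


def normalize_exposure_scale(xyz: np.ndarray, percentile: float = 99.9) -> float:
    """Exposure scale mapping the given luminance percentile to 1.0."""
    Y = xyz[..., 1]
    ref = np.percentile(Y[Y > 0], percentile) if np.any(Y > 0) else 1.0
    return 1.0 / ref if ref > 0 else 1.0


def srgb_encode(linear: np.ndarray) -> np.ndarray:
    """IEC 61966-2-1 transfer function, input clipped to [0, 1]."""
    c = np.clip(linear, 0.0, 1.0)
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * c ** (1.0 / 2.4) - 0.055)


def xyz_to_srgb_absolute(xyz: np.ndarray, exposure_scale: float = 1.0) -> ColorImage:
    """Absolute colorimetric intent: linear transform then per-channel
    clipping of out-of-gamut values."""
    if not exposure_scale > 0:
        raise ValueError("exposure scale must be positive")
    lin = np.einsum("hwc,dc->hwd", xyz * exposure_scale, XYZ_TO_LINEAR_SRGB)
    out_of_gamut = np.any((lin < -1e-9) | (lin > 1.0 + 1e-9), axis=-1)
    clip_fraction = float(np.mean(out_of_gamut))
    return ColorImage(data=srgb_encode(lin), space="sRGB-absolute",
                      chroma_scale=1.0, clip_fraction=clip_fraction)


def _xyz_to_oklab(xyz: np.ndarray) -> np.ndarray:
    lms = np.einsum("...c,dc->...d", xyz, _OKLAB_M1)
    lms = np.cbrt(lms)
    return np.einsum("...c,dc->...d", lms, _OKLAB_M2)


def _oklab_to_xyz(lab: np.ndarray) -> np.ndarray:
    lms = np.einsum("...c,dc->...d", lab, np.linalg.inv(_OKLAB_M2))
    lms = lms**3
    return np.einsum("...c,dc->...d", lms, np.linalg.inv(_OKLAB_M1))


def _gamut_violation(lab: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Per-pixel mask of Oklab colours falling outside the sRGB cube."""
    xyz = _oklab_to_xyz(lab)
    lin = np.einsum("...c,dc->...d", xyz, XYZ_TO_LINEAR_SRGB)
    return np.any((lin < -tol) | (lin > 1.0 + tol), axis=-1)


def xyz_to_srgb_perceptual(xyz: np.ndarray, exposure_scale: float = 1.0,
                           tol: float = 1e-3,
                           luminance_floor: float = 1e-3,
                           highlight_ceiling: float = 0.95) -> ColorImage:
    """Perceptual intent: uniform chroma desaturation until in gamut.

    Luminance is first limited to the display range (preserving
    chromaticity), then a single global scale ``s`` on the Oklab chroma
    plane is found by bisection — the largest value in (0, 1] for which
    every visually significant pixel maps inside the sRGB cube. Per-pixel
    hue angle and lightness are untouched, and chroma ratios between
    pixels are preserved exactly.

    Pixels darker than ``luminance_floor`` or brighter than
    ``highlight_ceiling`` (relative to display white) are excluded from
    the global search: a single Monte-Carlo noise pixel with a
    near-monochromatic spectrum, or a highlight pinned against the
    display ceiling where no chroma fits, would otherwise dictate the
    whole image's saturation. Those pixels are desaturated individually
    (hue and lightness still preserved) so the output never clips.
    """
    if not exposure_scale > 0:
        raise ValueError("exposure scale must be positive")
    xyz = xyz * exposure_scale
    Y = xyz[..., 1]
    # clip luminance while preserving chromaticity
    with np.errstate(divide="ignore", invalid="ignore"):
        lum_scale = np.where(Y > 1.0, 1.0 / np.maximum(Y, 1e-300), 1.0)
    xyz = xyz * lum_scale[..., None]
    lab = _xyz_to_oklab(xyz)
    # tone-limit: lightness above the display ceiling can never be fit
    # by desaturation alone
    lab[..., 0] = np.clip(lab[..., 0], 0.0, 1.0)
    # the global scale is set by visible, non-highlight pixels; pixels
    # near the lightness ceiling have no gamut headroom and are rescued
    # individually below, like any clipped highlight
    significant = (Y >= luminance_floor) & (Y <= highlight_ceiling)

    def scaled(s: float) -> np.ndarray:
        out = lab.copy()
        out[..., 1:] *= s
        return out

    def feasible(s: float) -> bool:
        bad = _gamut_violation(scaled(s))
        return not np.any(bad & significant)

    if feasible(1.0):
        s = 1.0
    else:
        lo, hi = 0.0, 1.0
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if feasible(mid):
                lo = mid
            else:
                hi = mid
        s = lo
    lab_out = scaled(s)
    # per-pixel rescue of sub-floor outliers: shrink their chroma until
    # they fit, leaving hue and lightness intact
    bad = _gamut_violation(lab_out)
    if np.any(bad):
        factors = np.ones(int(bad.sum()))
        sub = lab_out[bad]
        lo_v = np.zeros_like(factors)
        hi_v = np.ones_like(factors)
        for _ in range(24):
            mid = 0.5 * (lo_v + hi_v)
            test = sub.copy()
            test[:, 1:] *= mid[:, None]
            viol = _gamut_violation(test)
            lo_v = np.where(~viol, mid, lo_v)
            hi_v = np.where(viol, mid, hi_v)
        sub[:, 1:] *= lo_v[:, None]
        lab_out[bad] = sub
    lin = np.einsum("...c,dc->...d", _oklab_to_xyz(lab_out), XYZ_TO_LINEAR_SRGB)
    lin = np.clip(lin, 0.0, 1.0)  # numeric dust only; construction fits the gamut
    return ColorImage(data=srgb_encode(lin), space="sRGB-perceptual",
                      chroma_scale=s, clip_fraction=0.0)


def cie_lightness(Y: np.ndarray) -> np.ndarray:
    """CIE 1976 L* from relative luminance (white at Y = 1)."""
    Y = np.asarray(Y, dtype=float)
    delta = 6.0 / 29.0
    f = np.where(Y > delta**3, np.cbrt(np.maximum(Y, 0.0)),
                 Y / (3.0 * delta**2) + 4.0 / 29.0)
    return 116.0 * f - 16.0


def lightness_image(xyz: np.ndarray, exposure_scale: float = 1.0) -> ColorImage:
    """Grayscale rendering of per-pixel perceptual lightness.

    Equal-luminance pixels map to identical gray; the mapping is
    monotone in luminance. Stored channel value is L*/100.
    """
    if not exposure_scale > 0:
        raise ValueError("exposure scale must be positive")
    Y = np.clip(xyz[..., 1] * exposure_scale, 0.0, 1.0)
    g = np.clip(cie_lightness(Y) / 100.0, 0.0, 1.0)
    return ColorImage(data=np.repeat(g[..., None], 3, axis=-1),
                      space="lightness", chroma_scale=1.0, clip_fraction=0.0)
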