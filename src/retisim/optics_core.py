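"""Geometric-optical primitives for sequential Monte-Carlo ray tracing.

Provides dispersive material models, rotationally symmetric surface
geometry (conic aspheres, zonally deformed profiles, planes and stops),
vectorised Snell refraction, sequential surface-by-surface propagation
of ray bundles, and a stochastic ray-bending approximation of aperture
diffraction.

Conventions
-----------
* Optical axis is +z, pointing from object space toward the detector.
* Origin at the first surface vertex; lengths in mm.
* Wavelengths in micrometres; angles in radians.
* Surface radius ``R`` is positive when the centre of curvature lies on
  the +z side of the vertex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "LAMBDA_F",
    "LAMBDA_D",
    "LAMBDA_C",
    "VISIBLE_RANGE",
    "MaterialSpec",
    "DispersionModel",
    "AIR",
    "fit_dispersion",
    "evaluate_index",
    "Ray",
    "RayBundle",
    "RadialDeformation",
    "RampPlateauDeformation",
    "WindowedPolyDeformation",
    "Surface",
    "ConicSurface",
    "PlaneSurface",
    "StopSurface",
    "ZonalSurface",
    "OpticalStack",
    "refract",
    "intersect",
    "trace_sequential",
    "hurb_bend",
    "hurb_sigma",
]

# Fraunhofer F, d, C lines (micrometres)
LAMBDA_F = 0.48613
LAMBDA_D = 0.58756
LAMBDA_C = 0.65627

#: configured visible wavelength range (micrometres)
VISIBLE_RANGE = (0.38, 0.78)


# ---------------------------------------------------------------------------
# Dispersion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialSpec:
    """Optical material summarised by centre index and Abbe number.

    Parameters
    ----------
    n_d : float
        Refractive index at the helium d line (587.56 nm). Must exceed 1.
    V_d : float
        Abbe number ``(n_d - 1) / (n_F - n_C)``. Must be positive; use
        ``math.inf`` for a dispersionless material.
    """

    n_d: float
    V_d: float

    def __post_init__(self) -> None:
        if not self.n_d > 1.0:
            raise ValueError(f"centre index must exceed 1, got n_d={self.n_d}")
        if not self.V_d > 0.0:
            raise ValueError(f"Abbe number must be positive, got V_d={self.V_d}")


@dataclass(frozen=True)
class DispersionModel:
    """Two-coefficient index model  n(lambda) = A + B / (lambda^2 - lambda0^2).

    ``lambda0_sq`` (um^2) sets the steepness of the violet-side rise; 0
    recovers a two-term Cauchy model. ``B >= 0`` corresponds to normal
    dispersion.
    """

    A: float
    B: float
    lambda0_sq: float = 0.014

    def n(self, wavelength):
        """Refractive index at ``wavelength`` (um, scalar or array)."""
        wl = np.asarray(wavelength, dtype=float)
        denom = wl * wl - self.lambda0_sq
        if np.any(denom <= 0):
            raise ValueError(
                f"wavelength at or below the model pole sqrt({self.lambda0_sq}) um"
            )
        out = self.A + self.B / denom
        return float(out) if np.isscalar(wavelength) else out

    @property
    def n_d(self) -> float:
        return self.n(LAMBDA_D)

    @property
    def V_d(self) -> float:
        dn = self.n(LAMBDA_F) - self.n(LAMBDA_C)
        if dn == 0.0:
            return math.inf
        return (self.n(LAMBDA_D) - 1.0) / dn


#: ambient medium (vacuum/air, dispersionless)
AIR = DispersionModel(A=1.0, B=0.0)


def fit_dispersion(spec: MaterialSpec, lambda0_sq: float = 0.014) -> DispersionModel:
    """Fit the two-coefficient dispersion model to a (n_d, V_d) pair.

    Closed form: the model is linear in (A, B), so requiring
    ``n(lambda_d) = n_d`` and ``n(lambda_F) - n(lambda_C) = (n_d - 1)/V_d``
    determines both coefficients exactly.
    """
    if lambda0_sq >= LAMBDA_F**2:
        raise ValueError("lambda0_sq must lie below the F-line wavelength squared")
    if math.isinf(spec.V_d):
        return DispersionModel(A=spec.n_d, B=0.0, lambda0_sq=lambda0_sq)
    inv_f = 1.0 / (LAMBDA_F**2 - lambda0_sq)
    inv_c = 1.0 / (LAMBDA_C**2 - lambda0_sq)
    inv_d = 1.0 / (LAMBDA_D**2 - lambda0_sq)
    B = (spec.n_d - 1.0) / spec.V_d / (inv_f - inv_c)
    A = spec.n_d - B * inv_d
    return DispersionModel(A=A, B=B, lambda0_sq=lambda0_sq)


def evaluate_index(model: DispersionModel, wavelength) -> float:
    """Evaluate ``model`` at ``wavelength`` (um)."""
    return model.n(wavelength)


# ---------------------------------------------------------------------------
# Rays
# ---------------------------------------------------------------------------

@dataclass
class Ray:
    """A single Monte-Carlo sample: position (mm), unit direction,
    wavelength (um) and relative radiant weight."""

    origin: np.ndarray
    direction: np.ndarray
    wavelength: float
    weight: float = 1.0
    alive: bool = True

    def to_bundle(self) -> "RayBundle":
        return RayBundle(
            origin=np.asarray(self.origin, dtype=float)[None, :],
            direction=np.asarray(self.direction, dtype=float)[None, :],
            wavelength=np.array([self.wavelength]),
            weight=np.array([float(self.weight)]),
            alive=np.array([self.alive]),
        )


@dataclass
class RayBundle:
    """Structure-of-arrays container for N rays.

    ``origin``/``direction`` are (N, 3); ``wavelength`` (um), ``weight``
    and ``alive`` are (N,). Directions are unit vectors. Dead rays keep
    their last valid state but take no further part in propagation.
    """

    origin: np.ndarray
    direction: np.ndarray
    wavelength: np.ndarray
    weight: np.ndarray
    alive: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.atleast_2d(np.asarray(self.origin, dtype=float))
        self.direction = np.atleast_2d(np.asarray(self.direction, dtype=float))
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        self.alive = np.asarray(self.alive, dtype=bool)
        norms = np.linalg.norm(self.direction, axis=1)
        bad = self.alive & (np.abs(norms - 1.0) > 1e-9)
        if np.any(bad):
            self.direction = self.direction / norms[:, None]
        if np.any(self.weight < 0):
            raise ValueError("ray weights must be non-negative")

    @property
    def n(self) -> int:
        return self.origin.shape[0]

    def copy(self) -> "RayBundle":
        return RayBundle(
            self.origin.copy(),
            self.direction.copy(),
            self.wavelength.copy(),
            self.weight.copy(),
            self.alive.copy(),
        )

    @classmethod
    def parallel(cls, heights, wavelength, z: float = -1.0) -> "RayBundle":
        """Axis-parallel rays at the given x-heights (test helper)."""
        h = np.asarray(heights, dtype=float)
        n = h.size
        origin = np.column_stack([h, np.zeros(n), np.full(n, z)])
        direction = np.tile([0.0, 0.0, 1.0], (n, 1))
        wl = np.full(n, wavelength, dtype=float)
        return cls(origin, direction, wl, np.ones(n), np.ones(n, bool))


# ---------------------------------------------------------------------------
# Radial deformations (zonal surface profiles)
# ---------------------------------------------------------------------------

def _smoothstep(t):
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _smoothstep_d(t):
    inside = (t > 0.0) & (t < 1.0)
    t = np.clip(t, 0.0, 1.0)
    return np.where(inside, 6.0 * t * (1.0 - t), 0.0)


class RadialDeformation:
    """Additive rotationally symmetric sag deformation delta(r)."""

    def value(self, r):  # pragma: no cover - interface
        raise NotImplementedError

    def slope(self, r):  # pragma: no cover - interface
        raise NotImplementedError

    def to_dict(self) -> dict:  # pragma: no cover - interface
        raise NotImplementedError


@dataclass(frozen=True)
class RampPlateauDeformation(RadialDeformation):
    """Annular curvature plateau producing a locally elevated power zone.

    The radial sag slope rises linearly from zero at ``r1`` to
    ``dc * (r2 - r1)`` at ``r2`` and ramps back to zero at ``r3``: the
    deformation adds a constant extra surface curvature ``dc`` (1/mm)
    over [r1, r2], a compensating negative curvature over [r2, r3], and
    leaves the slope untouched elsewhere. Beyond ``r3`` the surface is a
    pure axial offset (an elevated region), so the peripheral power is
    unchanged.
    """

    dc: float
    r1: float
    r2: float
    r3: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r1 < self.r2 < self.r3):
            raise ValueError("plateau radii must satisfy 0 <= r1 < r2 < r3")

    def slope(self, r):
        r = np.asarray(r, dtype=float)
        up = self.dc * (r - self.r1)
        down = self.dc * (self.r2 - self.r1) * (self.r3 - r) / (self.r3 - self.r2)
        out = np.zeros_like(r)
        out = np.where((r >= self.r1) & (r < self.r2), up, out)
        out = np.where((r >= self.r2) & (r < self.r3), down, out)
        return out

    def value(self, r):
        r = np.asarray(r, dtype=float)
        dc, r1, r2, r3 = self.dc, self.r1, self.r2, self.r3
        h12 = 0.5 * dc * (r2 - r1) ** 2
        # integral of the down-ramp from r2 to r
        def down_int(rr):
            m = dc * (r2 - r1) / (r3 - r2)
            return m * (r3 * (rr - r2) - 0.5 * (rr**2 - r2**2))
        h_total = h12 + down_int(np.asarray(r3))
        out = np.zeros_like(r)
        seg1 = (r >= r1) & (r < r2)
        seg2 = (r >= r2) & (r < r3)
        out = np.where(seg1, 0.5 * dc * (r - r1) ** 2, out)
        out = np.where(seg2, h12 + down_int(r), out)
        out = np.where(r >= r3, h_total, out)
        return out

    def to_dict(self) -> dict:
        return {"type": "ramp-plateau", "dc": self.dc, "r1": self.r1,
                "r2": self.r2, "r3": self.r3}


@dataclass(frozen=True)
class WindowedPolyDeformation(RadialDeformation):
    """Fourth/sixth-order polynomial deformation confined to an inner zone.

    delta(r) = a4 r^4 + a6 r^6 inside ``r_inner`` (sag coefficients in
    mm^-3 / mm^-5). Across the transition annulus [r_inner, r_outer] the
    radial slope fades smoothly (cubic smoothstep) from its zone-edge
    value to zero, and beyond ``r_outer`` the deformation is a constant
    axial offset: the outer zone keeps the unperturbed base profile. The
    construction is C0-continuous everywhere and C1 when the polynomial
    slope already vanishes at ``r_inner`` (a6 = -2/3 a4 / r_inner^2).
    """

    a4: float
    a6: float
    r_inner: float
    r_outer: float

    def __post_init__(self) -> None:
        if not (0.0 < self.r_inner < self.r_outer):
            raise ValueError("require 0 < r_inner < r_outer")

    def _edge_slope(self) -> float:
        return 4.0 * self.a4 * self.r_inner**3 + 6.0 * self.a6 * self.r_inner**5

    def slope(self, r):
        r = np.asarray(r, dtype=float)
        w_tr = self.r_outer - self.r_inner
        t = np.clip((r - self.r_inner) / w_tr, 0.0, 1.0)
        inner = 4.0 * self.a4 * r**3 + 6.0 * self.a6 * r**5
        trans = self._edge_slope() * (1.0 - _smoothstep(t))
        return np.where(r < self.r_inner, inner, trans)

    def value(self, r):
        r = np.asarray(r, dtype=float)
        w_tr = self.r_outer - self.r_inner
        t = np.clip((r - self.r_inner) / w_tr, 0.0, 1.0)
        v_edge = self.a4 * self.r_inner**4 + self.a6 * self.r_inner**6
        # integral of (1 - smoothstep): t - t^3 + t^4/2
        ramp = self._edge_slope() * w_tr * (t - t**3 + 0.5 * t**4)
        inner = self.a4 * r**4 + self.a6 * r**6
        return np.where(r < self.r_inner, inner, v_edge + ramp)

    def to_dict(self) -> dict:
        return {"type": "windowed-poly", "a4": self.a4, "a6": self.a6,
                "r_inner": self.r_inner, "r_outer": self.r_outer}


_DEFORMATION_TYPES = {
    "ramp-plateau": RampPlateauDeformation,
    "windowed-poly": WindowedPolyDeformation,
}


def deformation_from_dict(d: dict) -> RadialDeformation:
    kind = d["type"]
    cls = _DEFORMATION_TYPES[kind]
    kwargs = {k: v for k, v in d.items() if k != "type"}
    return cls(**kwargs)


# ---------------------------------------------------------------------------
# Surfaces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Surface:
    """Base rotationally symmetric surface at axial position ``vertex_z``."""

    vertex_z: float
    semi_diameter: float

    kind = "abstract"

    def sag(self, r):
        raise NotImplementedError

    def sag_slope(self, r):
        raise NotImplementedError

    @property
    def vertex_curvature(self) -> float:
        return 0.0

    def with_vertex_z(self, z: float) -> "Surface":
        return replace(self, vertex_z=z)

    def to_dict(self) -> dict:
        raise NotImplementedError


@dataclass(frozen=True)
class ConicSurface(Surface):
    """Conic asphere: z(r) = c r^2 / (1 + sqrt(1 - (1+k) c^2 r^2)) + poly.

    ``R`` is the signed vertex radius (mm, R > 0 curving toward +z);
    ``poly_coeffs`` are even-order coefficients (r^4, r^6, ...) in
    mm^(1-order).
    """

    R: float = math.inf
    k: float = 0.0
    poly_coeffs: tuple = ()

    kind = "conic-asphere"

    @property
    def c(self) -> float:
        return 0.0 if math.isinf(self.R) else 1.0 / self.R

    @property
    def vertex_curvature(self) -> float:
        return self.c

    def sag(self, r):
        r = np.asarray(r, dtype=float)
        c = self.c
        r2 = r * r
        arg = np.maximum(1.0 - (1.0 + self.k) * c * c * r2, 0.0)
        z = c * r2 / (1.0 + np.sqrt(arg))
        for i, a in enumerate(self.poly_coeffs):
            z = z + a * r2 ** (i + 2)
        return z

    def sag_slope(self, r):
        r = np.asarray(r, dtype=float)
        c = self.c
        r2 = r * r
        arg = np.maximum(1.0 - (1.0 + self.k) * c * c * r2, 1e-12)
        dz = c * r / np.sqrt(arg)
        for i, a in enumerate(self.poly_coeffs):
            p = 2 * (i + 2)
            dz = dz + p * a * r ** (p - 1)
        return dz

    def to_dict(self) -> dict:
        return {"kind": self.kind, "vertex_z": self.vertex_z,
                "semi_diameter": self.semi_diameter, "R": self.R,
                "k": self.k, "poly_coeffs": list(self.poly_coeffs)}


@dataclass(frozen=True)
class PlaneSurface(Surface):
    """Flat surface normal to the axis (detector / retina plane)."""

    kind = "plane"

    def sag(self, r):
        return np.zeros_like(np.asarray(r, dtype=float))

    def sag_slope(self, r):
        return np.zeros_like(np.asarray(r, dtype=float))

    def to_dict(self) -> dict:
        return {"kind": self.kind, "vertex_z": self.vertex_z,
                "semi_diameter": self.semi_diameter}


@dataclass(frozen=True)
class StopSurface(Surface):
    """Plane aperture stop; rays outside ``stop_diameter`` are vignetted."""

    stop_diameter: float = 3.0

    kind = "stop"

    def sag(self, r):
        return np.zeros_like(np.asarray(r, dtype=float))

    def sag_slope(self, r):
        return np.zeros_like(np.asarray(r, dtype=float))

    @property
    def aperture_radius(self) -> float:
        return 0.5 * self.stop_diameter

    def to_dict(self) -> dict:
        return {"kind": self.kind, "vertex_z": self.vertex_z,
                "semi_diameter": self.semi_diameter,
                "stop_diameter": self.stop_diameter}


@dataclass(frozen=True)
class ZonalSurface(Surface):
    """Conic base profile plus a radial zonal deformation."""

    R: float = math.inf
    k: float = 0.0
    poly_coeffs: tuple = ()
    deformation: Optional[RadialDeformation] = None

    kind = "radial-zonal-profile"

    @property
    def base(self) -> ConicSurface:
        return ConicSurface(self.vertex_z, self.semi_diameter, self.R, self.k,
                            self.poly_coeffs)

    @property
    def vertex_curvature(self) -> float:
        return self.base.vertex_curvature

    def sag(self, r):
        z = self.base.sag(r)
        if self.deformation is not None:
            z = z + self.deformation.value(r)
        return z

    def sag_slope(self, r):
        dz = self.base.sag_slope(r)
        if self.deformation is not None:
            dz = dz + self.deformation.slope(r)
        return dz

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "vertex_z": self.vertex_z,
             "semi_diameter": self.semi_diameter, "R": self.R, "k": self.k,
             "poly_coeffs": list(self.poly_coeffs)}
        if self.deformation is not None:
            d["deformation"] = self.deformation.to_dict()
        return d


def surface_from_dict(d: dict) -> Surface:
    kind = d["kind"]
    if kind == "conic-asphere":
        return ConicSurface(d["vertex_z"], d["semi_diameter"], d["R"], d["k"],
                            tuple(d.get("poly_coeffs", ())))
    if kind == "plane":
        return PlaneSurface(d["vertex_z"], d["semi_diameter"])
    if kind == "stop":
        return StopSurface(d["vertex_z"], d["semi_diameter"], d["stop_diameter"])
    if kind == "radial-zonal-profile":
        deform = None
        if "deformation" in d:
            deform = deformation_from_dict(d["deformation"])
        return ZonalSurface(d["vertex_z"], d["semi_diameter"], d["R"], d["k"],
                            tuple(d.get("poly_coeffs", ())), deform)
    raise ValueError(f"unknown surface kind {kind!r}")


# ---------------------------------------------------------------------------
# Optical stack
# ---------------------------------------------------------------------------

@dataclass
class OpticalStack:
    """Ordered surface sequence with the medium following each surface.

    ``media[i]`` is the dispersion model of the gap after ``surfaces[i]``;
    ``ambient`` is the medium before the first surface.
    """

    surfaces: Sequence[Surface]
    media: Sequence[DispersionModel]
    ambient: DispersionModel = field(default_factory=lambda: AIR)

    def __post_init__(self) -> None:
        if len(self.surfaces) != len(self.media):
            raise ValueError("need one trailing medium per surface")
        zs = [s.vertex_z for s in self.surfaces]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValueError(f"surfaces must be strictly ordered in z, got {zs}")
        stops = [s for s in self.surfaces if isinstance(s, StopSurface)]
        if len(stops) > 1:
            raise ValueError("at most one aperture stop per stack")

    @property
    def stop(self) -> Optional[StopSurface]:
        for s in self.surfaces:
            if isinstance(s, StopSurface):
                return s
        return None

    def to_dict(self) -> dict:
        return {
            "ambient": {"A": self.ambient.A, "B": self.ambient.B,
                        "lambda0_sq": self.ambient.lambda0_sq},
            "elements": [
                {"surface": s.to_dict(),
                 "medium": {"A": m.A, "B": m.B, "lambda0_sq": m.lambda0_sq}}
                for s, m in zip(self.surfaces, self.media)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalStack":
        amb = DispersionModel(**d["ambient"])
        surfaces = [surface_from_dict(e["surface"]) for e in d["elements"]]
        media = [DispersionModel(**e["medium"]) for e in d["elements"]]
        return cls(surfaces, media, amb)


# ---------------------------------------------------------------------------
# Refraction
# ---------------------------------------------------------------------------

def refract(direction, normal, n1, n2):
    """Vector Snell refraction.

    Parameters are broadcastable arrays: unit incident directions (N, 3),
    unit surface normals (N, 3) (orientation is resolved internally), and
    per-ray indices. Returns ``(transmitted, tir)`` where ``tir`` marks
    rays that underwent total internal reflection (their direction is
    left unchanged and they should be killed by the caller).
    """
    d = np.atleast_2d(np.asarray(direction, dtype=float))
    nrm = np.atleast_2d(np.asarray(normal, dtype=float))
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    # orient normals against the incident ray so cos_i >= 0
    cos_i = -np.sum(d * nrm, axis=1)
    flip = cos_i < 0
    nrm = np.where(flip[:, None], -nrm, nrm)
    cos_i = np.abs(cos_i)
    eta = n1 / n2
    sin2_t = eta**2 * np.maximum(1.0 - cos_i**2, 0.0)
    tir = sin2_t > 1.0
    cos_t = np.sqrt(np.maximum(1.0 - sin2_t, 0.0))
    t = eta[..., None] * d + (eta * cos_i - cos_t)[:, None] * nrm
    t = np.where(tir[:, None], d, t)
    norm = np.linalg.norm(t, axis=1, keepdims=True)
    t = t / np.where(norm == 0, 1.0, norm)
    if np.asarray(direction).ndim == 1:
        return t[0], bool(tir[0])
    return t, tir


# ---------------------------------------------------------------------------
# Intersection
# ---------------------------------------------------------------------------

_NEWTON_TOL = 1e-9
_NEWTON_MAXIT = 50


def _intersect_plane(bundle: RayBundle, surface: Surface):
    dz = bundle.direction[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (surface.vertex_z - bundle.origin[:, 2]) / dz
    ok = np.isfinite(t) & (t > -1e-9) & (dz != 0)
    return t, ok


def _intersect_conic(bundle: RayBundle, surface: ConicSurface):
    """Analytic intersection with a pure conic (no poly terms).

    Solves the implicit conic equation
    ``c (x^2 + y^2) - 2 u + (1+k) c u^2 = 0`` with ``u = z - vertex_z``
    along the ray, choosing the root nearest the vertex plane.
    """
    c = surface.c
    o = bundle.origin.copy()
    o[:, 2] -= surface.vertex_z
    d = bundle.direction
    if c == 0.0:
        return _intersect_plane(bundle, surface)
    k1 = 1.0 + surface.k
    # quadratic A t^2 + B t + C = 0
    A = c * (d[:, 0] ** 2 + d[:, 1] ** 2) + c * k1 * d[:, 2] ** 2
    B = 2.0 * c * (o[:, 0] * d[:, 0] + o[:, 1] * d[:, 1]) \
        + 2.0 * c * k1 * o[:, 2] * d[:, 2] - 2.0 * d[:, 2]
    C = c * (o[:, 0] ** 2 + o[:, 1] ** 2) + c * k1 * o[:, 2] ** 2 - 2.0 * o[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        disc = B * B - 4.0 * A * C
        ok = disc >= 0
        sq = np.sqrt(np.maximum(disc, 0.0))
        # numerically stable roots
        q = -0.5 * (B + np.sign(B + (B == 0)) * sq)
        t1 = np.where(A != 0, q / np.where(A != 0, A, 1.0), -C / np.where(B != 0, B, 1.0))
        t2 = np.where(A != 0, C / np.where(q != 0, q, 1.0), t1)
    # pick the smallest root with positive path that stays near the vertex
    roots = np.stack([t1, t2], axis=1)
    z_hit = o[:, 2, None] + roots * d[:, 2, None]
    # valid: forward and sag within the hemisphere containing the vertex
    valid = (roots > -1e-9) & np.isfinite(roots)
    if c != 0.0 and k1 > 0:
        # closed conic: keep the near-side branch
        valid &= np.abs(z_hit) <= abs(1.0 / (c * k1)) + 1e-9 if k1 != 0 else True
    roots = np.where(valid, roots, np.inf)
    t = np.min(roots, axis=1)
    ok = ok & np.isfinite(t)
    return t, ok


def intersect(bundle: RayBundle, surface: Surface):
    """Intersect a bundle with a surface.

    Returns ``(points, normals, hit)``: intersection points (N, 3),
    outward unit normals (N, 3) with positive z component, and a boolean
    mask of rays with a forward intersection inside ``semi_diameter``.
    Conic and plane surfaces are solved analytically; aspheric/zonal
    profiles refine the base-conic root with a damped Newton iteration
    (tolerance 1e-9 mm).
    """
    if isinstance(surface, (PlaneSurface, StopSurface)):
        t, ok = _intersect_plane(bundle, surface)
    elif isinstance(surface, ConicSurface) and not surface.poly_coeffs:
        t, ok = _intersect_conic(bundle, surface)
    else:
        base = ConicSurface(surface.vertex_z, surface.semi_diameter,
                            surface.R, surface.k)
        t, ok = _intersect_conic(bundle, base)
        # fall back to the vertex plane when the conic solve failed
        t_pl, ok_pl = _intersect_plane(bundle, surface)
        t = np.where(ok, t, t_pl)
        ok = ok | ok_pl
        o, d = bundle.origin, bundle.direction
        for _ in range(_NEWTON_MAXIT):
            p = o + t[:, None] * d
            r = np.hypot(p[:, 0], p[:, 1])
            f = p[:, 2] - surface.vertex_z - surface.sag(r)
            if np.all(np.abs(f[ok]) < _NEWTON_TOL):
                break
            slope = surface.sag_slope(r)
            with np.errstate(divide="ignore", invalid="ignore"):
                drdt = np.where(r > 0, (p[:, 0] * d[:, 0] + p[:, 1] * d[:, 1]) / r, 0.0)
            fp = d[:, 2] - slope * drdt
            fp = np.where(np.abs(fp) < 1e-12, 1e-12, fp)
            step = f / fp
            step = np.clip(step, -1.0, 1.0)  # damping
            t = t - np.where(ok, step, 0.0)
        p = o + t[:, None] * d
        r = np.hypot(p[:, 0], p[:, 1])
        f = p[:, 2] - surface.vertex_z - surface.sag(r)
        ok = ok & (np.abs(f) < 1e-6) & (t > -1e-9)
    points = bundle.origin + t[:, None] * bundle.direction
    r = np.hypot(points[:, 0], points[:, 1])
    hit = ok & (r <= surface.semi_diameter + 1e-12)
    # outward normal from the analytic sag gradient, oriented toward +z
    slope = surface.sag_slope(np.maximum(r, 1e-15))
    with np.errstate(divide="ignore", invalid="ignore"):
        nx = np.where(r > 0, -slope * points[:, 0] / np.maximum(r, 1e-15), 0.0)
        ny = np.where(r > 0, -slope * points[:, 1] / np.maximum(r, 1e-15), 0.0)
    normals = np.column_stack([nx, ny, np.ones_like(nx)])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return points, normals, hit


# ---------------------------------------------------------------------------
# HURB diffraction approximation
# ---------------------------------------------------------------------------

def hurb_sigma(rho, wavelength_um, aperture_radius):
    """Angular bending scales (radial, tangential) at the stop plane.

    Each scale is lambda / (2 pi d) with d the distance to the aperture
    edge along the corresponding principal direction: the radial gap
    ``a - rho`` and the tangential half-chord ``sqrt(a^2 - rho^2)``.
    """
    rho = np.asarray(rho, dtype=float)
    lam_mm = np.asarray(wavelength_um, dtype=float) * 1e-3
    a = aperture_radius
    d_rad = np.maximum(a - rho, 1e-9)
    d_tan = np.sqrt(np.maximum(a * a - rho * rho, 1e-18))
    return lam_mm / (2.0 * np.pi * d_rad), lam_mm / (2.0 * np.pi * d_tan)


def hurb_bend(bundle: RayBundle, stop: StopSurface, rng: np.random.Generator) -> RayBundle:
    """Apply Heisenberg-uncertainty ray bending at an aperture stop.

    Rays inside the aperture receive independent zero-mean Gaussian
    angular perturbations along the radial and tangential directions;
    rays outside are vignetted. The bundle must already sit on the stop
    plane. Modifies and returns the bundle.
    """
    x, y = bundle.origin[:, 0], bundle.origin[:, 1]
    rho = np.hypot(x, y)
    inside = rho <= stop.aperture_radius
    bundle.alive &= inside
    act = bundle.alive
    if not np.any(act):
        return bundle
    sig_r, sig_t = hurb_sigma(rho, bundle.wavelength, stop.aperture_radius)
    # radial/tangential unit vectors in the stop plane (x-axis on axis)
    with np.errstate(invalid="ignore"):
        er = np.where(rho[:, None] > 0,
                      np.column_stack([x, y, np.zeros_like(x)]) / np.maximum(rho, 1e-300)[:, None],
                      np.tile([1.0, 0.0, 0.0], (bundle.n, 1)))
    et = np.column_stack([-er[:, 1], er[:, 0], np.zeros_like(x)])
    dth_r = rng.standard_normal(bundle.n) * sig_r
    dth_t = rng.standard_normal(bundle.n) * sig_t
    d = bundle.direction + dth_r[:, None] * er + dth_t[:, None] * et
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    bundle.direction = np.where(act[:, None], d, bundle.direction)
    return bundle


# ---------------------------------------------------------------------------
# Sequential tracing
# ---------------------------------------------------------------------------

def trace_sequential(bundle: RayBundle, stack: OpticalStack,
                     rng: Optional[np.random.Generator] = None,
                     apply_hurb: bool = True) -> RayBundle:
    """Propagate a bundle surface-by-surface through the stack.

    Rays are intersected with each surface in order, vignetted when they
    miss or fall outside the clear semi-diameter, refracted with the
    wavelength-dependent indices of the bounding media, and (optionally,
    when ``rng`` is given) diffraction-bent at the aperture stop. No
    absorption is modelled: surviving weights are unchanged. Total
    internal reflection kills the ray.

    Returns the modified bundle positioned on the final surface.
    """
    bundle = bundle.copy()
    current = stack.ambient
    for surface, after in zip(stack.surfaces, stack.media):
        if not np.any(bundle.alive):
            break
        points, normals, hit = intersect(bundle, surface)
        bundle.alive &= hit
        bundle.origin = np.where(bundle.alive[:, None], points, bundle.origin)
        if isinstance(surface, StopSurface):
            rho = np.hypot(bundle.origin[:, 0], bundle.origin[:, 1])
            if rng is not None and apply_hurb:
                bundle = hurb_bend(bundle, surface, rng)
            else:
                bundle.alive &= rho <= surface.aperture_radius
        elif isinstance(surface, PlaneSurface):
            pass  # detector or dummy plane: no index change handled below
        if not isinstance(surface, StopSurface):
            n1 = current.n(bundle.wavelength)
            n2 = after.n(bundle.wavelength)
            if not (current == after):
                new_dir, tir = refract(bundle.direction, normals, n1, n2)
                bundle.alive &= ~tir
                bundle.direction = np.where(bundle.alive[:, None], new_dir,
                                            bundle.direction)
        current = after
    return bundle
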