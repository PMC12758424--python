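"""Eye models, intraocular lens designs and optical-power metrics.

Builds the phakic Arizona-style schematic eye and its pseudophakic
variant with a parametric IOL placed at a given anterior chamber depth
(ACD). Ships generators for three packaged lens emulations — an aspheric
monofocal, an annular-plateau EDoF and a zonal spherical-aberration
EDoF — plus radial power profiles, chromatic refraction differences and
through-focus / depth-of-focus metrics.

The in-situ radial power convention used throughout: ``P(r)`` is the
lens's labelled power plus the object vergence (in D) that brings a
narrow parallel pencil passing the lens at radial height ``r`` to a
focus on the retina. A perfectly focused emmetropic configuration
therefore reads exactly the labelled power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence, Union

import numpy as np

from .optics_core import (
    AIR,
    LAMBDA_D,
    ConicSurface,
    DispersionModel,
    MaterialSpec,
    OpticalStack,
    PlaneSurface,
    RampPlateauDeformation,
    RayBundle,
    StopSurface,
    Surface,
    WindowedPolyDeformation,
    ZonalSurface,
    fit_dispersion,
    trace_sequential,
)

__all__ = [
    "ALCON_MATERIAL",
    "BAUSCH_MATERIAL",
    "ARIZONA",
    "EyeModel",
    "IOLDesign",
    "PseudophakicEye",
    "PowerProfile",
    "build_arizona_eye",
    "build_aphakic_eye",
    "assemble_pseudophakic",
    "make_monofocal_iol",
    "make_plateau_edof_iol",
    "make_zonal_sa_edof_iol",
    "packaged_iol",
    "packaged_eye",
    "PACKAGED_LENSES",
    "PACKAGED_ACD",
    "radial_power_profile",
    "chromatic_refraction_difference",
    "paraxial_focus_vergence",
    "through_focus_curve",
    "depth_of_focus",
    "retinal_scale_mm_per_deg",
]

# hydrophobic acrylic materials of the emulated lens families
ALCON_MATERIAL = MaterialSpec(n_d=1.5542, V_d=37.0)
BAUSCH_MATERIAL = MaterialSpec(n_d=1.540, V_d=43.0)


# ---------------------------------------------------------------------------
# Arizona-style schematic eye prescription (Schwiegerling)
# ---------------------------------------------------------------------------

#: prescription constants; ``A`` below denotes accommodation in diopters
ARIZONA = {
    "cornea_anterior": {"R": 7.8, "k": -0.25},
    "cornea_posterior": {"R": 6.5, "k": -0.25},
    "cornea_thickness": 0.55,
    "aqueous_thickness": lambda A: 2.97 - 0.04 * A,
    "lens_anterior": lambda A: {"R": 12.0 - 0.4 * A, "k": -7.518749 + 1.285720 * A},
    "lens_posterior": lambda A: {"R": -5.224557 + 0.2 * A, "k": -1.353971 - 0.431762 * A},
    "lens_thickness": lambda A: 3.767 + 0.04 * A,
    "axial_length": 24.0,
    # (n_d, V_d) of the ocular media
    "cornea_index": (1.377, 57.1),
    "aqueous_index": (1.337, 61.3),
    "lens_index": lambda A: (1.42 + 0.00256 * A - 0.00022 * A * A, 51.9),
    "vitreous_index": (1.336, 61.1),
}

_CORNEA = fit_dispersion(MaterialSpec(*ARIZONA["cornea_index"]))
_AQUEOUS = fit_dispersion(MaterialSpec(*ARIZONA["aqueous_index"]))
_VITREOUS = fit_dispersion(MaterialSpec(*ARIZONA["vitreous_index"]))

_EYE_SEMI_DIAM = 6.0
_IOL_SEMI_DIAM = 3.0
_PSEUDOPHAKIC_STOP_Z = 3.52  # iris plane, corneal vertex reference (mm)


@dataclass
class EyeModel:
    """Ordered ocular surface stack ending at a planar retina."""

    stack: OpticalStack
    pupil_diameter: float
    retina_z: float
    accommodation: float = 0.0
    label: str = "arizona-phakic"

    @property
    def stop_index(self) -> int:
        for i, s in enumerate(self.stack.surfaces):
            if isinstance(s, StopSurface):
                return i
        raise ValueError("eye stack has no aperture stop")

    def with_pupil(self, diameter: float) -> "EyeModel":
        """Copy of the eye with a different pupil diameter."""
        surfaces = list(self.stack.surfaces)
        i = self.stop_index
        surfaces[i] = replace(surfaces[i], stop_diameter=diameter)
        new = replace(self)
        new.stack = OpticalStack(surfaces, list(self.stack.media), self.stack.ambient)
        new.pupil_diameter = diameter
        return new


@dataclass(frozen=True)
class IOLDesign:
    """Parametric biconvex intraocular lens.

    Surface ``vertex_z`` values are relative to the anterior vertex
    (anterior at 0, posterior at ``center_thickness``).
    """

    label: str
    anterior: Surface
    posterior: Surface
    center_thickness: float
    material: MaterialSpec
    nominal_power: float

    def __post_init__(self) -> None:
        if self.anterior.semi_diameter < 3.0 or self.posterior.semi_diameter < 3.0:
            raise ValueError("IOL semi-diameters must cover at least 3.0 mm")

    @property
    def dispersion(self) -> DispersionModel:
        return fit_dispersion(self.material)


@dataclass
class PseudophakicEye(EyeModel):
    """Eye with the crystalline lens replaced by an IOL at depth ``acd``."""

    iol: Optional[IOLDesign] = None
    acd: float = 4.15
    label: str = "pseudophakic"

    @property
    def iol_anterior_index(self) -> int:
        return self.stop_index + 1


@dataclass
class PowerProfile:
    """Radial in-situ optical power samples P(r)."""

    r: np.ndarray
    power: np.ndarray
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Eye builders
# ---------------------------------------------------------------------------

def build_arizona_eye(accommodation: float = 0.0,
                      pupil_diameter: float = 3.0) -> EyeModel:
    """Phakic schematic eye at the given accommodation level (diopters)."""
    if accommodation < 0:
        raise ValueError("accommodation must be non-negative")
    A = accommodation
    rx = ARIZONA
    t_c = rx["cornea_thickness"]
    z_lens = t_c + rx["aqueous_thickness"](A)
    z_lens_post = z_lens + rx["lens_thickness"](A)
    retina_z = rx["axial_length"]
    lens_ant = rx["lens_anterior"](A)
    lens_post = rx["lens_posterior"](A)
    lens_medium = fit_dispersion(MaterialSpec(*rx["lens_index"](A)))
    surfaces = [
        ConicSurface(0.0, _EYE_SEMI_DIAM, **rx["cornea_anterior"]),
        ConicSurface(t_c, _EYE_SEMI_DIAM, **rx["cornea_posterior"]),
        StopSurface(z_lens - 0.06, _EYE_SEMI_DIAM, stop_diameter=pupil_diameter),
        ConicSurface(z_lens, 5.0, **lens_ant),
        ConicSurface(z_lens_post, 5.0, **lens_post),
        PlaneSurface(retina_z, _EYE_SEMI_DIAM),
    ]
    media = [_CORNEA, _AQUEOUS, _AQUEOUS, lens_medium, _VITREOUS, _VITREOUS]
    stack = OpticalStack(surfaces, media, AIR)
    return EyeModel(stack, pupil_diameter, retina_z, accommodation=A)


def build_aphakic_eye(pupil_diameter: float = 3.0) -> EyeModel:
    """Cornea + pupil + retina only; template for pseudophakic assembly."""
    rx = ARIZONA
    t_c = rx["cornea_thickness"]
    retina_z = rx["axial_length"]
    surfaces = [
        ConicSurface(0.0, _EYE_SEMI_DIAM, **rx["cornea_anterior"]),
        ConicSurface(t_c, _EYE_SEMI_DIAM, **rx["cornea_posterior"]),
        StopSurface(_PSEUDOPHAKIC_STOP_Z, _EYE_SEMI_DIAM,
                    stop_diameter=pupil_diameter),
        PlaneSurface(retina_z, _EYE_SEMI_DIAM),
    ]
    media = [_CORNEA, _AQUEOUS, _AQUEOUS, _VITREOUS]
    stack = OpticalStack(surfaces, media, AIR)
    return EyeModel(stack, pupil_diameter, retina_z, label="aphakic")


def assemble_pseudophakic(eye: EyeModel, iol: IOLDesign, acd: float) -> PseudophakicEye:
    """Insert ``iol`` with its anterior vertex at ``acd`` into the eye.

    The crystalline lens (if present) is discarded; aqueous fills the
    space up to the IOL and vitreous the space behind it.
    """
    retina_z = eye.retina_z
    if acd <= _PSEUDOPHAKIC_STOP_Z:
        raise ValueError(f"acd={acd} mm would place the IOL inside the anterior chamber stop")
    if acd + iol.center_thickness >= retina_z:
        raise ValueError(f"acd={acd} mm puts the IOL at or behind the retina")
    rx = ARIZONA
    t_c = rx["cornea_thickness"]
    surfaces = [
        ConicSurface(0.0, _EYE_SEMI_DIAM, **rx["cornea_anterior"]),
        ConicSurface(t_c, _EYE_SEMI_DIAM, **rx["cornea_posterior"]),
        StopSurface(_PSEUDOPHAKIC_STOP_Z, _EYE_SEMI_DIAM,
                    stop_diameter=eye.pupil_diameter),
        iol.anterior.with_vertex_z(acd + iol.anterior.vertex_z),
        iol.posterior.with_vertex_z(acd + iol.posterior.vertex_z),
        PlaneSurface(retina_z, _EYE_SEMI_DIAM),
    ]
    media = [_CORNEA, _AQUEOUS, _AQUEOUS, iol.dispersion, _VITREOUS, _VITREOUS]
    stack = OpticalStack(surfaces, media, AIR)
    return PseudophakicEye(stack, eye.pupil_diameter, retina_z,
                           label=f"pseudophakic-{iol.label}", iol=iol, acd=acd)


# ---------------------------------------------------------------------------
# Paraxial tracing
# ---------------------------------------------------------------------------

def _paraxial_trace(eye: EyeModel, wavelength: float, y0: float, u0: float):
    """First-order (y, u) trace; returns retina height and per-surface heights."""
    y, u = y0, u0
    z_prev = 0.0
    n_cur = eye.stack.ambient.n(wavelength)
    heights = []
    for surf, medium in zip(eye.stack.surfaces, eye.stack.media):
        y = y + u * (surf.vertex_z - z_prev)
        heights.append(y)
        n_next = medium.n(wavelength)
        if not isinstance(surf, (StopSurface, PlaneSurface)) and n_next != n_cur:
            c = surf.vertex_curvature
            u = (n_cur * u - y * c * (n_next - n_cur)) / n_next
        n_cur = n_next
        z_prev = surf.vertex_z
    return y, heights


def paraxial_focus_vergence(eye: EyeModel, wavelength: float = LAMBDA_D) -> float:
    """Object vergence (D) whose paraxial image lands on the retina.

    Positive values mean the eye is myopic at this wavelength (a near
    object is in focus).
    """
    y_a, _ = _paraxial_trace(eye, wavelength, 1.0, 0.0)
    y_b, _ = _paraxial_trace(eye, wavelength, 1.0, 1.0 / 1000.0)  # V = 1 D
    if y_b == y_a:
        raise ValueError("degenerate paraxial system: retina height independent of vergence")
    return -y_a / (y_b - y_a)


def paraxial_defocus_at_retina(eye: EyeModel, wavelength: float = LAMBDA_D) -> float:
    """Alias of :func:`paraxial_focus_vergence` (refractive error in D)."""
    return paraxial_focus_vergence(eye, wavelength)


def chromatic_refraction_difference(eye: EyeModel,
                                    lambda_short: float,
                                    lambda_long: float) -> float:
    """Difference of best-focus object vergences V(short) - V(long), in D.

    Positive when short wavelengths are more myopic (the normal ocular
    chromatic ordering: blue focus anterior to red).
    """
    if lambda_short > lambda_long:
        raise ValueError("lambda_short must not exceed lambda_long")
    return (paraxial_focus_vergence(eye, lambda_short)
            - paraxial_focus_vergence(eye, lambda_long))


def retinal_scale_mm_per_deg(eye: EyeModel, wavelength: float = LAMBDA_D,
                             field_deg: float = 1.0) -> float:
    """Retinal image height per degree of object field angle.

    Calibrated with a real traced chief ray (entrance position solved so
    the ray crosses the stop centre) at ``field_deg``, which captures the
    true field mapping including distortion better than a first-order
    trace does.
    """
    theta = math.radians(field_deg)
    d = np.array([math.sin(theta), 0.0, math.cos(theta)])
    i_stop = eye.stop_index
    stop_z = eye.stack.surfaces[i_stop].vertex_z
    open_eye = _open_pupil(eye)
    sub = OpticalStack(list(open_eye.stack.surfaces[: i_stop + 1]),
                       list(open_eye.stack.media[: i_stop + 1]),
                       open_eye.stack.ambient)

    def stop_height(x0: float) -> float:
        b = RayBundle(np.array([[x0, 0.0, -1.0]]), d[None, :],
                      np.array([wavelength]), np.array([1.0]), np.array([True]))
        out = trace_sequential(b, sub, rng=None)
        return float(out.origin[0, 0]) if out.alive[0] else math.nan

    # secant solve for the chief ray's entrance position
    x0, x1 = 0.0, -0.5
    f0, f1 = stop_height(x0), stop_height(x1)
    for _ in range(12):
        if math.isnan(f1) or f1 == f0:
            break
        x2 = x1 - f1 * (x1 - x0) / (f1 - f0)
        x0, f0, x1, f1 = x1, f1, x2, stop_height(x2)
        if abs(f1) < 1e-10:
            break
    b = RayBundle(np.array([[x1, 0.0, -1.0]]), d[None, :],
                  np.array([wavelength]), np.array([1.0]), np.array([True]))
    out = trace_sequential(b, open_eye.stack, rng=None)
    if not out.alive[0]:
        raise ValueError("chief ray vignetted while calibrating the retinal scale")
    return abs(float(out.origin[0, 0])) / field_deg


# ---------------------------------------------------------------------------
# Real-ray pencil focusing
# ---------------------------------------------------------------------------

def _open_pupil(eye: EyeModel) -> EyeModel:
    return eye.with_pupil(2.0 * _EYE_SEMI_DIAM)


def _pencil_bundle(heights, vergence_D: float, wavelength: float) -> RayBundle:
    """Rays from an axial object point at the given vergence, aimed at
    the stated entrance heights on the first-surface plane."""
    h = np.asarray(heights, dtype=float)
    n = h.size
    dx = h * vergence_D / 1000.0
    d = np.column_stack([dx, np.zeros(n), np.ones(n)])
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    z0 = -1.0
    x0 = h + d[:, 0] / d[:, 2] * z0
    origin = np.column_stack([x0, np.zeros(n), np.full(n, z0)])
    return RayBundle(origin, d, np.full(n, wavelength), np.ones(n), np.ones(n, bool))


def _pencil_separation(eye: EyeModel, center_height: float, vergence_D: float,
                       wavelength: float, half_width: float) -> float:
    b = _pencil_bundle([center_height - half_width, center_height + half_width],
                       vergence_D, wavelength)
    out = trace_sequential(b, eye.stack, rng=None)
    if not np.all(out.alive):
        return math.nan
    return float(out.origin[1, 0] - out.origin[0, 0])


def pencil_focus_vergence(eye: EyeModel, entrance_height: float,
                          wavelength: float = LAMBDA_D,
                          half_width: float = 0.025) -> float:
    """Object vergence at which a narrow pencil entering at
    ``entrance_height`` focuses on the retina (secant solve; NaN when the
    pencil is vignetted)."""
    open_eye = _open_pupil(eye)
    v0, v1 = 0.0, 1.0
    f0 = _pencil_separation(open_eye, entrance_height, v0, wavelength, half_width)
    f1 = _pencil_separation(open_eye, entrance_height, v1, wavelength, half_width)
    if math.isnan(f0) or math.isnan(f1):
        return math.nan
    for _ in range(8):
        if f1 == f0:
            break
        v2 = v1 - f1 * (v1 - v0) / (f1 - f0)
        f2 = _pencil_separation(open_eye, entrance_height, v2, wavelength, half_width)
        if math.isnan(f2):
            return math.nan
        v0, f0, v1, f1 = v1, f1, v2, f2
        if abs(f1) < 1e-10:
            break
    return v1


def _height_at_surface(eye: EyeModel, surf_index: int, entrance_height: float,
                       wavelength: float) -> float:
    """Radial height of a parallel entrance ray at a given stack surface."""
    surfaces = list(eye.stack.surfaces[: surf_index + 1])
    media = list(eye.stack.media[: surf_index + 1])
    sub = OpticalStack(surfaces, media, eye.stack.ambient)
    b = _pencil_bundle([entrance_height], 0.0, wavelength)
    out = trace_sequential(b, sub, rng=None)
    if not out.alive[0]:
        return math.nan
    return float(out.origin[0, 0])


def _entrance_height_for_lens_radius(eye: PseudophakicEye, r_lens: float,
                                     wavelength: float) -> float:
    """Entrance height whose ray meets the IOL anterior surface at r_lens."""
    if r_lens == 0.0:
        return 0.0
    open_eye = _open_pupil(eye)
    idx = eye.iol_anterior_index
    h0, h1 = r_lens, r_lens * 1.3
    f0 = _height_at_surface(open_eye, idx, h0, wavelength) - r_lens
    f1 = _height_at_surface(open_eye, idx, h1, wavelength) - r_lens
    for _ in range(10):
        if math.isnan(f0) or math.isnan(f1) or f1 == f0:
            return math.nan if math.isnan(f1) else h1
        h2 = h1 - f1 * (h1 - h0) / (f1 - f0)
        f2 = _height_at_surface(open_eye, idx, h2, wavelength) - r_lens
        h0, f0, h1, f1 = h1, f1, h2, f2
        if abs(f1) < 1e-8:
            break
    return h1


def radial_power_profile(eye: PseudophakicEye, r_grid,
                         wavelength: float = LAMBDA_D,
                         pencil_half_width: float = 0.025) -> PowerProfile:
    """In-situ radial power profile P(r) of the implanted lens.

    For each lens radius ``r`` a narrow parallel pencil is aimed so it
    crosses the IOL anterior surface at ``r``; the object vergence that
    focuses the pencil on the retina is added to the labelled lens power.
    Vignetted pencils are reported as NaN, not interpolated.
    """
    r_grid = np.asarray(r_grid, dtype=float)
    if r_grid.size == 0:
        raise ValueError("empty radius grid")
    if np.any(np.diff(r_grid) <= 0) and r_grid.size > 1:
        raise ValueError("radius grid must be strictly increasing")
    powers = np.empty_like(r_grid)
    for i, r in enumerate(r_grid):
        h = _entrance_height_for_lens_radius(eye, float(r), wavelength)
        if math.isnan(h):
            powers[i] = math.nan
            continue
        v = pencil_focus_vergence(eye, h, wavelength, pencil_half_width)
        powers[i] = eye.iol.nominal_power + v if not math.isnan(v) else math.nan
    meta = {
        "convention": "labelled power + object vergence focused on retina",
        "wavelength_um": wavelength,
        "pencil_half_width_mm": pencil_half_width,
        "lens": eye.iol.label,
        "acd_mm": eye.acd,
    }
    return PowerProfile(r=r_grid, power=powers, metadata=meta)


# ---------------------------------------------------------------------------
# IOL generators
# ---------------------------------------------------------------------------

def _reference_eye(iol: IOLDesign, acd: float, pupil: float = 3.0) -> PseudophakicEye:
    return assemble_pseudophakic(build_aphakic_eye(pupil), iol, acd)


def _aqueous_index() -> float:
    return _AQUEOUS.n(LAMBDA_D)


def make_monofocal_iol(power: float = 20.0,
                       material: MaterialSpec = ALCON_MATERIAL,
                       *,
                       center_thickness: float = 0.6,
                       reference_acd: float = 4.15,
                       label: str = "monofocal") -> IOLDesign:
    """Equiconvex aspheric monofocal lens.

    Radii are solved so the in-situ d-line power in the reference
    pseudophakic eye equals ``power`` (paraxially exact); the anterior
    conic constant is then solved so the real-ray power profile is flat
    across the aperture (aberration-controlled design).
    """
    if not 10.0 <= power <= 30.0:
        raise ValueError(f"power {power} D outside the supported [10, 30] D range")
    n_l, n_aq = material.n_d, _aqueous_index()
    R0 = 2.0 * (n_l - n_aq) * 1000.0 / power  # thin-lens equiconvex start

    def build(scale: float, k_ant: float, a4: float = 0.0) -> IOLDesign:
        ant = ConicSurface(0.0, _IOL_SEMI_DIAM, R=R0 / scale, k=k_ant,
                           poly_coeffs=(a4,) if a4 else ())
        post = ConicSurface(center_thickness, _IOL_SEMI_DIAM, R=-R0 / scale, k=0.0)
        return IOLDesign(label, ant, post, center_thickness, material, power)

    from scipy.optimize import brentq, least_squares

    def defocus(scale: float) -> float:
        eye = _reference_eye(build(scale, 0.0), reference_acd)
        return paraxial_focus_vergence(eye, LAMBDA_D)

    try:
        scale = brentq(defocus, 0.5, 1.6, xtol=1e-10)
    except ValueError as exc:
        raise ValueError(f"requested power {power} D unreachable for the allowed "
                         f"curvature range") from exc

    # flatten the real-ray profile: conic constant + one even asphere term
    # solved so mid-zone and peripheral pencils match the central focus
    def residuals(params):
        k_ant, a4 = params
        eye = _reference_eye(build(scale, k_ant, a4), reference_acd)
        v0 = pencil_focus_vergence(eye, 0.3, LAMBDA_D)
        return [pencil_focus_vergence(eye, 1.4, LAMBDA_D) - v0,
                pencil_focus_vergence(eye, 2.4, LAMBDA_D) - v0]

    sol = least_squares(residuals, x0=[-20.0, 0.0], xtol=1e-10, ftol=1e-12,
                        diff_step=1e-3)
    k_ant, a4 = float(sol.x[0]), float(sol.x[1])
    return build(scale, k_ant, a4)


#: default plateau zone radii (mm) and ramp end of the emulated design
_PLATEAU_R3 = 1.35


def make_plateau_edof_iol(power: float = 20.0,
                          zone_inner: float = 0.55,
                          zone_outer: float = 1.1,
                          add: float = 2.0,
                          material: MaterialSpec = ALCON_MATERIAL,
                          *,
                          ramp_outer: Optional[float] = None,
                          center_thickness: float = 0.6,
                          reference_acd: float = 4.10,
                          label: str = "plateau-edof") -> IOLDesign:
    """EDoF lens with a raised annular power zone on the anterior surface.

    ``add`` is the target in-situ power elevation (object-vergence D) of
    the annulus [zone_inner, zone_outer] relative to the periphery. The
    deformation is calibrated against the traced power profile so the
    elevation matches ``add``; beyond the ramp the anterior surface is a
    pure axial offset, leaving the peripheral power at the base value.
    """
    if not 0.0 < zone_inner < zone_outer:
        raise ValueError("zone radii must satisfy 0 < zone_inner < zone_outer")
    r3 = ramp_outer if ramp_outer is not None else max(_PLATEAU_R3, zone_outer + 0.2)
    if not zone_outer < r3 <= _IOL_SEMI_DIAM:
        raise ValueError("ramp_outer must lie between zone_outer and the semi-diameter")
    base = make_monofocal_iol(power, material, center_thickness=center_thickness,
                              reference_acd=reference_acd, label=label)
    n_l, n_aq = material.n_d, _aqueous_index()

    def build(dc: float) -> IOLDesign:
        deform = RampPlateauDeformation(dc=dc, r1=zone_inner, r2=zone_outer, r3=r3)
        ant = base.anterior
        zonal = ZonalSurface(ant.vertex_z, ant.semi_diameter, R=ant.R, k=ant.k,
                             poly_coeffs=ant.poly_coeffs, deformation=deform)
        return replace(base, anterior=zonal)

    if add == 0.0:
        return build(0.0)
    # initial guess: surface-curvature equivalent with an IOL-to-object
    # vergence conversion factor ~0.75, then one measured refinement
    dc = add / (0.75 * (n_l - n_aq) * 1000.0)
    for _ in range(2):
        eye = _reference_eye(build(dc), reference_acd)
        r_mid = 0.5 * (zone_inner + zone_outer)
        prof = radial_power_profile(eye, np.array([r_mid, 0.5 * (r3 + _IOL_SEMI_DIAM)]))
        elevation = prof.power[0] - prof.power[1]
        if not np.isfinite(elevation) or elevation == 0:
            break
        dc *= add / elevation
    return build(dc)


def make_zonal_sa_edof_iol(power: float = 20.0,
                           inner_radius: float = 1.0,
                           sa4: float = 2.0,
                           sa6: float = -0.8,
                           material: MaterialSpec = BAUSCH_MATERIAL,
                           *,
                           transition_outer: float = 1.3,
                           center_thickness: float = 0.6,
                           reference_acd: float = 3.91,
                           label: str = "zonal-sa-edof") -> IOLDesign:
    """EDoF lens with an inner zone of mixed 4th/6th-order spherical
    aberration of opposite signs, a C0-continuous transition annulus and
    an unperturbed aberration-free outer zone.

    ``sa4``/``sa6`` are wavefront coefficients in waves at 0.55 um across
    ``inner_radius``, converted to surface sag through the in-situ index
    step.
    """
    if sa4 * sa6 > 0:
        raise ValueError("sa4 and sa6 must have opposite signs")
    if not 0 < inner_radius < transition_outer <= _IOL_SEMI_DIAM:
        raise ValueError("require 0 < inner_radius < transition_outer <= semi-diameter")
    base = make_monofocal_iol(power, material, center_thickness=center_thickness,
                              reference_acd=reference_acd, label=label)
    if sa4 == 0.0 and sa6 == 0.0:
        ant = base.anterior
        zonal = ZonalSurface(ant.vertex_z, ant.semi_diameter, R=ant.R, k=ant.k,
                             poly_coeffs=ant.poly_coeffs, deformation=None)
        return replace(base, anterior=zonal)
    lam_mm = 0.55e-3
    n_step = material.n_d - _aqueous_index()
    a4 = sa4 * lam_mm / n_step / inner_radius**4
    a6 = sa6 * lam_mm / n_step / inner_radius**6
    deform = WindowedPolyDeformation(a4=a4, a6=a6, r_inner=inner_radius,
                                     r_outer=transition_outer)
    ant = base.anterior
    zonal = ZonalSurface(ant.vertex_z, ant.semi_diameter, R=ant.R, k=ant.k,
                         poly_coeffs=ant.poly_coeffs, deformation=deform)
    return replace(base, anterior=zonal)


# ---------------------------------------------------------------------------
# Packaged lens models
# ---------------------------------------------------------------------------

#: anterior chamber depths of the packaged configurations (mm)
PACKAGED_ACD = {"monofocal": 4.15, "plateau-edof": 4.10, "zonal-sa-edof": 3.91}

PACKAGED_LENSES = tuple(PACKAGED_ACD)


@lru_cache(maxsize=None)
def packaged_iol(lens: str) -> IOLDesign:
    """One of the three packaged 20 D lens emulations."""
    if lens == "monofocal":
        return make_monofocal_iol(20.0, ALCON_MATERIAL, reference_acd=4.15)
    if lens == "plateau-edof":
        return make_plateau_edof_iol(20.0, material=ALCON_MATERIAL,
                                     reference_acd=4.10)
    if lens == "zonal-sa-edof":
        return make_zonal_sa_edof_iol(20.0, material=BAUSCH_MATERIAL,
                                      reference_acd=3.91)
    raise ValueError(f"unknown packaged lens {lens!r}; options: {PACKAGED_LENSES}")


def packaged_eye(lens: str, pupil_diameter: float = 3.0) -> PseudophakicEye:
    """Pseudophakic eye carrying a packaged lens at its nominal ACD."""
    iol = packaged_iol(lens)
    eye = assemble_pseudophakic(build_aphakic_eye(pupil_diameter), iol,
                                PACKAGED_ACD[lens])
    return eye


# ---------------------------------------------------------------------------
# Through-focus metrics
# ---------------------------------------------------------------------------

def _point_source_bundle(vergence_D: float, n_rays: int, aperture_radius: float,
                         wavelengths, rng: np.random.Generator,
                         target_z: float = _PSEUDOPHAKIC_STOP_Z,
                         margin: float = 1.12) -> RayBundle:
    """Rays from an on-axis point source filling the pupil (uniform
    aperture sampling; adequate for spot-spread metrics)."""
    a = aperture_radius * margin
    u = rng.random(n_rays)
    phi = rng.random(n_rays) * 2.0 * np.pi
    rt = a * np.sqrt(u)
    xt, yt = rt * np.cos(phi), rt * np.sin(phi)
    if vergence_D > 1e-9:
        s = 1000.0 / vergence_D
        d = np.column_stack([xt, yt, np.full(n_rays, s + target_z)])
    else:
        d = np.column_stack([np.zeros(n_rays), np.zeros(n_rays), np.ones(n_rays)])
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    # back-project to a start plane in front of the cornea
    z0 = -1.0
    L = (target_z - z0) / d[:, 2]
    origin = np.column_stack([xt, yt, np.full(n_rays, target_z)]) - L[:, None] * d
    wl = np.broadcast_to(np.asarray(wavelengths, dtype=float), (n_rays,)).copy()
    return RayBundle(origin, d, wl, np.ones(n_rays), np.ones(n_rays, bool))


def _sample_wavelengths(plan, n: int, rng: np.random.Generator):
    from .scene import SpectralSamplingPlan  # local import, avoids a cycle
    if isinstance(plan, SpectralSamplingPlan):
        idx = rng.choice(plan.n_bins, size=n, p=plan.weights)
        return plan.centers[idx]
    return np.full(n, float(plan))


def through_focus_curve(eye: PseudophakicEye, vergences: Sequence[float],
                        pupil: Optional[float] = None,
                        spectrum: Union[float, "SpectralSamplingPlan"] = LAMBDA_D,
                        n_rays: int = 20000, seed: int = 0,
                        apply_hurb: bool = False) -> np.ndarray:
    """RMS retinal spot radius (mm, weight-weighted) per object vergence.

    Lower values mean a sharper focus. Each vergence is traced with its
    own child generator derived from ``seed`` and the vergence value, so
    duplicate entries give bit-identical metrics. Aperture-diffraction
    ray bending is off by default: its heavy-tailed edge deflections
    dominate a second-moment metric (the diffraction pattern's second
    moment is unbounded) and would mask the through-focus behaviour.
    """
    vergences = list(vergences)
    if not vergences:
        raise ValueError("empty vergence list")
    if pupil is not None and pupil != eye.pupil_diameter:
        eye = eye.with_pupil(pupil)
    a = 0.5 * eye.pupil_diameter
    out = np.empty(len(vergences))
    for i, v in enumerate(vergences):
        rng = np.random.default_rng([seed, int(round(float(v) * 1e6)) & 0x7FFFFFFF])
        wl = _sample_wavelengths(spectrum, n_rays, rng)
        bundle = _point_source_bundle(float(v), n_rays, a, wl, rng)
        if not np.isscalar(spectrum) or isinstance(spectrum, str):
            # photopic spot metric: weight polychromatic rays by the
            # luminous efficiency of their wavelength
            from .retinal_render import _CMF, _CMF_WL_UM
            bundle.weight = bundle.weight * np.interp(wl, _CMF_WL_UM, _CMF[:, 1])
        traced = trace_sequential(bundle, eye.stack, rng=rng, apply_hurb=apply_hurb)
        alive = traced.alive
        if not np.any(alive):
            out[i] = math.inf
            continue
        w = traced.weight[alive]
        x, y = traced.origin[alive, 0], traced.origin[alive, 1]
        cx, cy = np.average(x, weights=w), np.average(y, weights=w)
        out[i] = math.sqrt(np.average((x - cx) ** 2 + (y - cy) ** 2, weights=w))
    return out


def depth_of_focus(vergences: Sequence[float], metric: Sequence[float],
                   criterion: float = 2.0) -> float:
    """Width (D) of the contiguous vergence interval with metric values
    at or below ``criterion`` times the curve minimum, around the
    minimum. Returns 0 when the criterion is never met."""
    v = np.asarray(vergences, dtype=float)
    m = np.asarray(metric, dtype=float)
    if v.size != m.size or v.size < 2:
        raise ValueError("vergences and metric must be equal-length (>= 2)")
    fine = np.arange(v.min(), v.max() + 1e-9, 0.01)
    mf = np.interp(fine, v, m)
    thresh = criterion * np.nanmin(mf)
    ok = mf <= thresh
    if not np.any(ok):
        return 0.0
    i0 = int(np.nanargmin(mf))
    lo = i0
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = i0
    while hi < ok.size - 1 and ok[hi + 1]:
        hi += 1
    return float(fine[hi] - fine[lo])
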