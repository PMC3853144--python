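"""Closed-form mechanical surrogates for the fluid–structure stress fields.

Arterial tissue is modelled as incompressible, isotropic and hyperelastic
with the modified Mooney–Rivlin strain-energy density

    W = c1*(I1 - 3) + c2*(I2 - 3) + D1*[exp(D2*(I1 - 3)) - 1]   (kPa),

where I1 and I2 are the first and second invariants of the right
Cauchy–Green tensor C = X^T X.  Four tissue presets (vessel/fibrous cap,
calcification, lipid-rich necrotic core, loose matrix) ship with the
package; c2 = 0 for all of them, the c2 term is kept so the energy form
is complete.

In vivo a carotid is axially stretched and pressurised, so simulations
start from a shrunk no-load geometry: 9% axial shrink (a 10% axial
stretch restores in vivo length) with circumferential lumen shrink
chosen so that wall material volume is conserved exactly
(:func:`shrink_noload_geometry`).

Full 3D fluid–structure interaction is out of scope here; plaque wall
stress (PWS) and flow shear stress (FSS) fields are painted on node
grids from thin-wall hoop stress P*r/h and Poiseuille wall shear
4*mu*Q/(pi*r^3), with seeded smooth angular/axial harmonics standing in
for plaque irregularity.  These are explicitly surrogate fields with the
right units, magnitudes and spatial smoothness, not solver output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from plaqueprog.vessel_geometry import NodeGrid, SLICE_SPACING_MM

DEFAULT_AXIAL_SHRINK = 0.09

TISSUE_LABELS = ("vessel", "calcification", "lipid", "loose_matrix")


@dataclass(frozen=True)
class MaterialParams:
    """Modified Mooney–Rivlin coefficients for one tissue type (kPa)."""

    c1: float
    c2: float
    d1: float
    d2: float
    tissue_label: str = "custom"

    def __post_init__(self) -> None:
        if self.c1 < 0 or self.d1 < 0 or self.d2 <= 0:
            raise ValueError("require c1 >= 0, D1 >= 0, D2 > 0")


def material_presets() -> dict[str, MaterialParams]:
    """The four packaged tissue parameter sets."""
    raw = json.loads(
        resources.files("plaqueprog.data").joinpath("material_presets.json").read_text()
    )
    return {
        label: MaterialParams(
            c1=v["c1_kpa"], c2=v["c2_kpa"], d1=v["d1_kpa"], d2=v["d2"],
            tissue_label=label,
        )
        for label, v in raw.items()
    }


def invariants_from_stretches(lam1: float, lam2: float, lam3: float):
    """First and second strain invariants from principal stretches.

    I1 = tr C and I2 = (I1^2 - tr(C^2))/2 with C = diag(lam_i^2).
    """
    lams = np.asarray([lam1, lam2, lam3], float)
    if np.any(lams <= 0):
        raise ValueError("principal stretches must be positive")
    sq = lams**2
    i1 = float(sq.sum())
    i2 = float(sq[0] * sq[1] + sq[1] * sq[2] + sq[0] * sq[2])
    return i1, i2


def strain_energy(params: MaterialParams, i1: float, i2: float) -> float:
    """Strain-energy density W (kPa); zero at the identity state (3, 3)."""
    if i1 < 3.0 - 1e-9:
        raise ValueError(f"I1 = {i1} below 3: not reachable by an incompressible state")
    i1 = max(i1, 3.0)
    return (
        params.c1 * (i1 - 3.0)
        + params.c2 * (i2 - 3.0)
        + params.d1 * (math.exp(params.d2 * (i1 - 3.0)) - 1.0)
    )


def uniaxial_cauchy_stress(params: MaterialParams, lam: float) -> float:
    """Uniaxial Cauchy stress (kPa) at stretch ``lam``, incompressible.

    For the uniaxial path (lam, lam^-1/2, lam^-1/2) the lateral stress is
    zero and sigma = 2*(lam^2 - 1/lam)*(dW/dI1 + (1/lam)*dW/dI2), with
    dW/dI1 = c1 + D1*D2*exp(D2*(I1-3)) and dW/dI2 = c2.
    """
    if lam <= 0:
        raise ValueError("stretch must be positive")
    i1 = lam**2 + 2.0 / lam
    dw_di1 = params.c1 + params.d1 * params.d2 * math.exp(params.d2 * (i1 - 3.0))
    dw_di2 = params.c2
    return 2.0 * (lam**2 - 1.0 / lam) * (dw_di1 + dw_di2 / lam)


@dataclass(frozen=True)
class VesselRingGeometry:
    """Idealised vessel ring: lumen radius, outer radius, length (mm)."""

    inner_radius: float
    outer_radius: float
    length: float

    def __post_init__(self) -> None:
        if not (0 < self.inner_radius < self.outer_radius):
            raise ValueError("require 0 < inner radius < outer radius")
        if self.length <= 0:
            raise ValueError("length must be positive")

    @property
    def wall_volume(self) -> float:
        return math.pi * (self.outer_radius**2 - self.inner_radius**2) * self.length


def shrink_noload_geometry(
    in_vivo: VesselRingGeometry,
    lumen_shrink: float,
    axial_shrink: float = DEFAULT_AXIAL_SHRINK,
) -> VesselRingGeometry:
    """No-load starting geometry under exact wall-volume conservation.

    Length shrinks by ``axial_shrink``, the lumen radius by
    ``lumen_shrink``; the no-load outer radius is the unique positive
    root of  pi*(ro0^2 - ri0^2)*L0 = pi*(ro^2 - ri^2)*L.
    """
    for name, s in (("lumen_shrink", lumen_shrink), ("axial_shrink", axial_shrink)):
        if not (0 <= s < 1):
            raise ValueError(f"{name} must lie in [0, 1)")
    l0 = (1.0 - axial_shrink) * in_vivo.length
    ri0 = (1.0 - lumen_shrink) * in_vivo.inner_radius
    ro0_sq = ri0**2 + (in_vivo.outer_radius**2 - in_vivo.inner_radius**2) * (
        in_vivo.length / l0
    )
    if ro0_sq <= ri0**2:  # cannot happen for valid inputs; guarded regardless
        raise ValueError("volume-conservation equation has no valid outer radius")
    return VesselRingGeometry(inner_radius=ri0, outer_radius=math.sqrt(ro0_sq), length=l0)


def implied_outer_shrink(
    in_vivo: VesselRingGeometry,
    lumen_shrink: float,
    axial_shrink: float = DEFAULT_AXIAL_SHRINK,
) -> float:
    """Fractional outer-wall shrink implied by volume conservation."""
    noload = shrink_noload_geometry(in_vivo, lumen_shrink, axial_shrink)
    return 1.0 - noload.outer_radius / in_vivo.outer_radius


def _harmonic_field(theta, z, rng, amplitude, n_modes=3):
    """Smooth positive multiplicative heterogeneity on (theta, z)."""
    field = np.ones_like(theta)
    span = max(z.max() - z.min(), SLICE_SPACING_MM)
    for m in range(1, n_modes + 1):
        a = amplitude * rng.uniform(0.3, 1.0) / m
        psi = rng.uniform(0, 2 * np.pi)
        xi = rng.uniform(0, 2 * np.pi)
        axial = np.cos(2 * np.pi * m * (z - z.min()) / (2.0 * span) + xi)
        field = field + a * np.cos(m * theta + psi) * (0.5 + 0.5 * axial)
    return np.clip(field, 0.2, None)


def paint_stress_fields(
    grid: NodeGrid,
    systolic_pressure_kpa: float = 16.0,
    viscosity_pa_s: float = 0.0035,
    flow_rate_ml_s: float = 6.0,
    heterogeneity_seed: int | None = None,
    heterogeneity_amplitude: float = 0.15,
) -> NodeGrid:
    """Paint surrogate PWS (kPa) and FSS (dyn/cm^2) fields on a grid.

    PWS = P * r / h per node (thin-wall hoop stress, local wall thickness
    h); FSS = 4*mu*Q/(pi*r^3) per slice (Poiseuille), converted from Pa
    to dyn/cm^2.  With ``heterogeneity_seed`` set, two independent seeded
    harmonic fields modulate PWS and FSS multiplicatively so the painted
    fields vary smoothly around the vessel the way solver output does.
    """
    if systolic_pressure_kpa <= 0 or viscosity_pa_s <= 0 or flow_rate_ml_s <= 0:
        raise ValueError("pressure, viscosity and flow rate must be positive")
    t = grid.table
    x = t["x_mm"].to_numpy(float)
    y = t["y_mm"].to_numpy(float)
    z = t["z_mm"].to_numpy(float)
    h = t["wall_thickness_mm"].to_numpy(float)
    r_mm = np.hypot(x, y)
    theta = np.arctan2(y, x)

    pws = systolic_pressure_kpa * r_mm / h  # kPa: kPa * mm / mm
    r_m = r_mm * 1e-3
    q_m3 = flow_rate_ml_s * 1e-6
    fss_pa = 4.0 * viscosity_pa_s * q_m3 / (np.pi * r_m**3)
    fss = fss_pa * 10.0  # 1 Pa = 10 dyn/cm^2

    if heterogeneity_seed is not None:
        ss = np.random.SeedSequence(heterogeneity_seed)
        rng_p, rng_f = (np.random.default_rng(s) for s in ss.spawn(2))
        pws = pws * _harmonic_field(theta, z, rng_p, heterogeneity_amplitude)
        fss = fss * _harmonic_field(theta, z, rng_f, heterogeneity_amplitude)

    out = t.copy()
    out["pws_kpa"] = pws
    out["fss_dyn_cm2"] = fss
    return NodeGrid(patient_id=grid.patient_id, scan_id=grid.scan_id, table=out)


def stress_stretch_curve(params: MaterialParams, lam_max: float = 1.8, n: int = 81):
    """(stretch, Cauchy stress kPa) samples on [1, lam_max] for one preset."""
    lams = np.linspace(1.0, lam_max, n)
    return lams, np.array([uniaxial_cauchy_stress(params, l) for l in lams])
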