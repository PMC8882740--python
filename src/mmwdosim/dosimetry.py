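"""Dosimetric quantities at the skin surface: transmittance, APD, ratios, compliance.

Transmittance is the net normal Poynting flux crossing the skin surface (z3)
divided by the incident normal flux IPD·cos θ0; the absorbed power density
(APD) is that same flux in W/m².  The two are therefore proportional by
construction, APD = T·IPD·cos θ0, and for a bare stack T reduces exactly to
1 − |γ|² at the air/skin interface.

A literal local form 1 − |γ2|², with γ2 the reflection coefficient of the
skin half-stack seen from the air side, is also exposed
(``transmittance_local``) for comparison; being a property of the skin stack
and angle alone it cannot depend on cloth or air gap.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import cos, radians

import numpy as np

from . import em_core
from .em_core import PlaneWaveExcitation, interface_reflection, solve_fields

__all__ = [
    "DosimetryResult",
    "ComplianceResult",
    "evaluate",
    "transmittance",
    "apd",
    "ratio_to_bare",
    "normalized_apd_db",
    "compliance_check",
    "BASIC_RESTRICTION_WM2",
]

#: local-exposure basic restriction for the general public above 6 GHz (W/m²)
BASIC_RESTRICTION_WM2 = 20.0


@dataclass
class DosimetryResult:
    """Per-evaluation dosimetry (entries may be vectorised arrays)."""

    transmittance: object
    apd: object          # W/m² at z3
    gamma_skin: object   # γ2: reflection coefficient at the air/skin interface
    transmittance_local: object  # literal 1 − |γ2|²
    theta0_deg: float
    polarization: str
    incident_power_density: float
    clothed: bool


def evaluate(stack, excitation: PlaneWaveExcitation) -> DosimetryResult:
    """Solve the stack and extract skin-surface dosimetry."""
    sol = solve_fields(stack, excitation)
    i3 = stack.skin_interface
    s3 = sol.interface_flux(i3)
    inc = excitation.incident_power_density * cos(radians(excitation.theta0_deg))
    # gap (or incidence half-space) above the skin is air: impedance Z[0]
    gamma2 = interface_reflection(sol.zin[i3], sol.Z[0])
    t_local = 1.0 - np.abs(gamma2) ** 2
    return DosimetryResult(
        transmittance=s3 / inc,
        apd=s3,
        gamma_skin=gamma2,
        transmittance_local=t_local,
        theta0_deg=excitation.theta0_deg,
        polarization=excitation.polarization,
        incident_power_density=excitation.incident_power_density,
        clothed=i3 > 1,
    )


def transmittance(stack, excitation: PlaneWaveExcitation):
    """Net-flux transmittance at the skin surface (dimensionless, ≤ 1)."""
    return evaluate(stack, excitation).transmittance


def apd(stack, excitation: PlaneWaveExcitation):
    """Absorbed power density at the skin surface, W/m² (≤ IPD·cos θ0)."""
    return evaluate(stack, excitation).apd


def ratio_to_bare(clothed_mean, bare_mean):
    """Clothed/bare quotient of matched mean statistics.

    Accepts scalars or arrays; a zero bare reference (possible only at
    degenerate grazing) raises.
    """
    bare = np.asarray(bare_mean, dtype=float)
    if np.any(bare == 0.0):
        raise ZeroDivisionError("bare-skin reference is zero")
    return np.asarray(clothed_mean, dtype=float) / bare


def normalized_apd_db(apd_mean_grid):
    """10·log10(mean APD / max mean APD) over one material–polarization surface.

    The maximum is taken over the supplied grid, so the peak cell maps to
    exactly 0 dB and everything else is ≤ 0.
    """
    grid = np.asarray(apd_mean_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty APD grid")
    peak = np.max(grid)
    if peak <= 0.0:
        raise ValueError("non-positive APD surface")
    return 10.0 * np.log10(grid / peak)


@dataclass(frozen=True)
class ComplianceResult:
    passed: bool
    margin_wm2: float
    basic_restriction_wm2: float
    max_apd_wm2: float


def compliance_check(apd_wm2, basic_restriction: float = BASIC_RESTRICTION_WM2) -> ComplianceResult:
    """Check APD against the local-exposure basic restriction (boundary inclusive)."""
    arr = np.asarray(apd_wm2, dtype=float)
    if np.any(arr < 0.0):
        raise ValueError("APD must be non-negative")
    worst = float(np.max(arr))
    return ComplianceResult(
        passed=bool(worst <= basic_restriction),
        margin_wm2=float(basic_restriction - worst),
        basic_restriction_wm2=float(basic_restriction),
        max_apd_wm2=worst,
    )
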