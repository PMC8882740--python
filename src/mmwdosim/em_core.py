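"""Plane-wave solver for lossy stratified media at oblique TE/TM incidence.

Transmission-line formulation of a planar multilayer: each layer carries a
forward and a backward wave of the tangential field pair (V, I) ≡ (E_t, H_t),
with V = Z·I for a single forward wave and the polarization-dependent wave
impedance Z.  Interfaces impose continuity of V and I; the normal Poynting
flux is ½·Re{V·I*} for both polarizations.

Conventions
-----------
* time factor e^{+jωt}; lossy permittivity ε = ε′ − jε″ (ε″ ≥ 0)
* propagation e^{−j k·r}; the longitudinal wavenumber branch has
  Im(k_z) ≤ 0 so transmitted waves decay with depth
* z = 0 at the first interface (air/cloth, or air/skin when bare),
  increasing into the body; external thickness I/O in millimetres, SI
  internally

The recursion propagates amplitude ratios (reflection coefficients), which is
the numerically stable form of the per-layer 2×2 wave matrices: the involved
exponentials e^{−2j k_z d} never exceed unit magnitude in passive layers.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import cos, radians, sin

import numpy as np
from scipy.constants import c as C0, epsilon_0 as EPS0, mu_0 as MU0

__all__ = [
    "TE",
    "TM",
    "ETA0",
    "DegenerateIncidenceError",
    "PlaneWaveExcitation",
    "FieldSolution",
    "transverse_wavenumber",
    "layer_kz",
    "wave_impedance",
    "interface_reflection",
    "cascade_input_impedance",
    "solve_fields",
    "poynting_normal",
]

TE = "TE"
TM = "TM"

#: free-space wave impedance, Ω
ETA0 = float(np.sqrt(MU0 / EPS0))

_MM = 1e-3


class DegenerateIncidenceError(ValueError):
    """Raised at exact grazing incidence where wave impedances degenerate."""


@dataclass(frozen=True)
class PlaneWaveExcitation:
    """Incident plane wave in the air half-space.

    ``incident_power_density`` is defined on the plane normal to the wave
    vector, so the normal flux onto the stack is IPD·cos θ0.
    """

    theta0_deg: float
    polarization: str
    frequency_hz: float = 60e9
    incident_power_density: float = 26.6

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta0_deg < 90.0:
            raise DegenerateIncidenceError(
                f"theta0_deg must be in [0, 90), got {self.theta0_deg}")
        if self.polarization not in (TE, TM):
            raise ValueError(f"polarization must be 'TE' or 'TM', got {self.polarization!r}")
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be positive")
        if self.incident_power_density <= 0:
            raise ValueError("incident_power_density must be positive")


def transverse_wavenumber(excitation: PlaneWaveExcitation) -> float:
    """Phase-matched transverse wavenumber k_y = k0 sin θ0 (rad/m)."""
    k0 = 2.0 * np.pi * excitation.frequency_hz / C0
    return k0 * sin(radians(excitation.theta0_deg))


def layer_kz(epsilon, k_y: float, frequency_hz: float):
    """Longitudinal wavenumber k_z = sqrt(k0²ε − k_y²), branch Im(k_z) ≤ 0.

    The principal square root already lands in the fourth quadrant for lossy
    ε = ε′ − jε″; the explicit flip covers the lossless evanescent case where
    the principal branch would give Im > 0.
    """
    k0 = 2.0 * np.pi * frequency_hz / C0
    kz = np.sqrt(k0 * k0 * np.asarray(epsilon, dtype=complex) - k_y * k_y)
    return np.where(kz.imag > 0.0, -kz, kz)[()]


def wave_impedance(epsilon, kz, polarization: str, frequency_hz: float):
    """Transverse wave impedance: TE → ωμ0/k_z, TM → k_z/(ωε0·ε)."""
    if np.any(kz == 0):
        raise DegenerateIncidenceError("k_z = 0: grazing/degenerate incidence")
    w = 2.0 * np.pi * frequency_hz
    if polarization == TE:
        return w * MU0 / kz
    if polarization == TM:
        return kz / (w * EPS0 * np.asarray(epsilon, dtype=complex))
    raise ValueError(f"unknown polarization {polarization!r}")


def interface_reflection(z_in_below, z_above):
    """Amplitude reflection coefficient γ = (Z_below − Z_above)/(Z_below + Z_above)."""
    return (z_in_below - z_above) / (z_in_below + z_above)


def _prepare(stack, excitation: PlaneWaveExcitation):
    """Per-layer k_z, Z and thickness (m) for a stack realization."""
    k_y = transverse_wavenumber(excitation)
    f = excitation.frequency_hz
    kz = [layer_kz(eps, k_y, f) for eps in stack.epsilon]
    zz = [wave_impedance(eps, k, excitation.polarization, f)
          for eps, k in zip(stack.epsilon, kz)]
    d_m = [None if t is None else np.asarray(t, dtype=float) * _MM
           for t in stack.thickness_mm]
    return k_y, kz, zz, d_m


def _cascade(kz, zz, d_m):
    """Bottom-up impedance cascade.

    Returns ``(zin, rb)`` where ``zin[i]`` is the input impedance looking
    toward the termination at the top of layer i (i ≥ 1) and ``rb[i]`` is the
    reflection coefficient at the bottom of layer i (i ≤ L−2).
    """
    L = len(kz)
    zin = [None] * L
    rb = [None] * L
    carry = zz[L - 1]
    zin[L - 1] = carry
    for i in range(L - 2, -1, -1):
        r = (carry - zz[i]) / (carry + zz[i])
        rb[i] = r
        if i == 0:
            break
        rt = r * np.exp(-2j * kz[i] * d_m[i])
        carry = zz[i] * (1.0 + rt) / (1.0 - rt)
        zin[i] = carry
    return zin, rb


def cascade_input_impedance(stack, excitation: PlaneWaveExcitation) -> list:
    """Input impedance looking toward the termination at the top of every layer.

    Element 0 (the incidence half-space, which has no top interface) is None;
    the terminating layer's entry is its own wave impedance.
    """
    _, kz, zz, d_m = _prepare(stack, excitation)
    zin, _ = _cascade(kz, zz, d_m)
    return zin


@dataclass
class FieldSolution:
    """Forward/backward amplitudes of the tangential fields in every layer.

    Amplitudes are referenced at each layer's top interface (the incidence
    half-space at z = 0).  Arrays broadcast when the stack carries vectorised
    thickness draws.
    """

    excitation: PlaneWaveExcitation
    names: tuple
    epsilon: tuple
    k_y: float
    kz: list
    Z: list
    d_m: list
    A: list
    B: list
    zin: list
    rb: list

    @property
    def n_layers(self) -> int:
        return len(self.names)

    def z_top_m(self, i: int):
        """Depth of the top interface of layer i (i ≥ 1)."""
        z = 0.0
        for j in range(1, i):
            z = z + self.d_m[j]
        return z

    def amplitudes_at(self, i: int, zeta_m):
        """(V, I) at local depth ``zeta_m`` below the top of layer i.

        For the incidence half-space ``zeta_m`` is negative (above z = 0).
        The backward wave is evaluated through the bottom-referenced product
        form, which stays well-scaled in thick lossy layers.
        """
        ph = np.exp(-1j * self.kz[i] * zeta_m)
        v_f = self.A[i] * ph
        if i == self.n_layers - 1:
            v_b = 0.0
        else:
            v_b = self.B[i] / ph if i == 0 else self._backward_at(i, zeta_m)
        V = v_f + v_b
        I = (v_f - v_b) / self.Z[i]
        return V, I

    def _backward_at(self, i: int, zeta_m):
        # B(ζ) = rb · A · e^{−jk(2d−ζ)}: decaying exponent for 0 ≤ ζ ≤ d
        return self.rb[i] * self.A[i] * np.exp(
            -1j * self.kz[i] * (2.0 * self.d_m[i] - zeta_m))

    def interface_flux(self, i: int):
        """Normal Poynting flux ½Re{V·I*} at the top interface of layer i."""
        V = self.A[i] + self.B[i]
        I = (self.A[i] - self.B[i]) / self.Z[i]
        return 0.5 * np.real(V * np.conj(I))

    def _locate(self, z_m: float, side: str):
        if z_m < 0.0 or (z_m == 0.0 and side == "above"):
            return 0, z_m
        top = 0.0
        for i in range(1, self.n_layers):
            if i == self.n_layers - 1:
                return i, z_m - top
            bottom = top + float(self.d_m[i])
            if z_m < bottom or (z_m == bottom and side == "above"):
                return i, z_m - top
            top = bottom
        raise ValueError("z outside stack")  # pragma: no cover

    def tangential_fields(self, z_mm: float, side: str = "below"):
        """(V, I) = (tangential E, tangential H) at depth z (scalar stacks)."""
        i, zeta = self._locate(float(z_mm) * _MM, side)
        return self.amplitudes_at(i, zeta)

    def poynting(self, z_mm: float, side: str = "below"):
        V, I = self.tangential_fields(z_mm, side)
        return float(0.5 * np.real(V * np.conj(I)))


def solve_fields(stack, excitation: PlaneWaveExcitation) -> FieldSolution:
    """Solve the multilayer boundary-value problem.

    The incident forward wave carries exactly ``incident_power_density`` on
    the wave-normal plane; the termination carries no backward wave.
    """
    _k_y, kz, zz, d_m = _prepare(stack, excitation)
    zin, rb = _cascade(kz, zz, d_m)
    L = len(kz)

    cth = cos(radians(excitation.theta0_deg))
    a0 = np.sqrt(2.0 * excitation.incident_power_density * cth * np.real(zz[0]))
    A = [None] * L
    B = [None] * L
    A[0] = a0 + 0j
    B[0] = rb[0] * a0
    V = A[0] + B[0]
    I = (A[0] - B[0]) / zz[0]
    for i in range(1, L):
        Ai = (V + zz[i] * I) / 2.0
        A[i] = Ai
        if i == L - 1:
            B[i] = np.zeros_like(Ai)
            break
        ph = np.exp(-1j * kz[i] * d_m[i])
        B[i] = rb[i] * ph * ph * Ai
        a_bot = Ai * ph
        b_bot = rb[i] * a_bot
        V = a_bot + b_bot
        I = (a_bot - b_bot) / zz[i]

    return FieldSolution(excitation, tuple(stack.names), tuple(stack.epsilon),
                         _k_y, kz, zz, d_m, A, B, zin, rb)


def poynting_normal(solution: FieldSolution, z_mm: float, side: str = "below") -> float:
    """½·Re{(E×H*)·n} at depth z, n pointing into the body (W/m²)."""
    return solution.poynting(z_mm, side)
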