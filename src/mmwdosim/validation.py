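"""Independent brute-force reference solver for cross-validation.

Instead of cascading layer matrices, this solver assembles the full linear
system of tangential-field continuity conditions at every interface
(2 equations per interface, unknown forward/backward amplitudes in every
layer) and solves it directly.  Backward amplitudes are referenced at each
layer's *bottom* interface so every matrix entry has magnitude ≤ 1 in passive
media and the system stays well conditioned even for optically thick lossy
layers.

Intended for tests and acceptance property checks only; the production path
is :mod:`mmwdosim.em_core`.
"""
from __future__ import annotations

from math import cos, radians

import numpy as np

from .em_core import PlaneWaveExcitation, _prepare

__all__ = ["solve_fields_direct", "skin_flux_direct"]


def solve_fields_direct(stack, excitation: PlaneWaveExcitation):
    """Solve interface continuity as one dense linear system.

    Returns ``(A, B)`` lists of complex amplitudes per layer, referenced at
    each layer's top interface (matching :func:`mmwdosim.em_core.solve_fields`).
    Scalar thicknesses only.
    """
    _k_y, kz, zz, d_m = _prepare(stack, excitation)
    L = len(kz)
    if L < 2:
        raise ValueError("need at least two layers")
    for d in d_m[1:-1]:
        if np.ndim(d) != 0:
            raise ValueError("direct solver handles scalar stacks only")

    cth = cos(radians(excitation.theta0_deg))
    a0 = complex(np.sqrt(2.0 * excitation.incident_power_density * cth * np.real(zz[0])))

    # unknowns: x = [B0, A1, Bb1, A2, Bb2, ..., A_{L-2}, Bb_{L-2}, A_{L-1}]
    # where Bbi is the backward amplitude of layer i referenced at its bottom
    n = 2 * (L - 1)
    M = np.zeros((n, n), dtype=complex)
    rhs = np.zeros(n, dtype=complex)

    def col_A(i):  # forward amplitude column of layer i (1 <= i <= L-1)
        return 2 * i - 1

    def col_Bb(i):  # bottom-referenced backward column of layer i (1 <= i <= L-2)
        return 2 * i

    phase = [None] * L
    for i in range(1, L - 1):
        phase[i] = np.exp(-1j * kz[i] * float(d_m[i]))

    for j in range(L - 1):  # interface j: bottom of layer j / top of layer j+1
        rV, rI = 2 * j, 2 * j + 1
        # above side: layer j evaluated at its bottom
        if j == 0:
            # layer 0 referenced at z = 0: V = a0 + B0, I = (a0 − B0)/Z0
            M[rV, 0] += 1.0
            M[rI, 0] += -1.0 / zz[0]
            rhs[rV] += -a0
            rhs[rI] += -a0 / zz[0]
        else:
            pj = phase[j]
            M[rV, col_A(j)] += pj
            M[rV, col_Bb(j)] += 1.0
            M[rI, col_A(j)] += pj / zz[j]
            M[rI, col_Bb(j)] += -1.0 / zz[j]
        # below side: layer j+1 evaluated at its top (negated)
        i = j + 1
        M[rV, col_A(i)] -= 1.0
        M[rI, col_A(i)] -= 1.0 / zz[i]
        if i <= L - 2:
            pi = phase[i]
            M[rV, col_Bb(i)] -= pi
            M[rI, col_Bb(i)] -= -pi / zz[i]
        # terminating layer has no backward wave

    x = np.linalg.solve(M, rhs)
    A = [a0 + 0j] + [x[col_A(i)] for i in range(1, L)]
    B = [x[0]]
    for i in range(1, L - 1):
        B.append(x[col_Bb(i)] * phase[i])  # re-reference at layer top
    B.append(0j)
    return A, B


def skin_flux_direct(stack, excitation: PlaneWaveExcitation) -> float:
    """Normal Poynting flux at the skin surface from the direct solve (W/m²)."""
    _k_y, kz, zz, d_m = _prepare(stack, excitation)
    A, B = solve_fields_direct(stack, excitation)
    i3 = stack.skin_interface
    V = A[i3] + B[i3]
    I = (A[i3] - B[i3]) / zz[i3]
    return float(0.5 * np.real(V * np.conj(I)))
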