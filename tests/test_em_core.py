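"""Stratified-media solver: closed-form limits, invariants and oracle equivalence."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.constants import c as C0

from mmwdosim import (
    ETA0,
    DegenerateIncidenceError,
    PlaneWaveExcitation,
    StackRealization,
    cascade_input_impedance,
    interface_reflection,
    layer_kz,
    solve_fields,
    transverse_wavenumber,
    wave_impedance,
)
from mmwdosim.validation import solve_fields_direct

from conftest import mean_bare_stack, random_lossy_stack, excitations

F = 60e9
K0 = 2 * np.pi * F / C0

# sqrt(8.5 - 9.9j) evaluated with 30-digit symbolic arithmetic
SQRT_EPI = 3.28240548576083469 - 1.50804037510698669j


def test_transverse_wavenumber_limits():
    assert transverse_wavenumber(PlaneWaveExcitation(0.0, "TE", F)) == 0.0
    k30 = transverse_wavenumber(PlaneWaveExcitation(30.0, "TM", F))
    assert k30 == pytest.approx(K0 / 2, rel=1e-12)
    k89 = transverse_wavenumber(PlaneWaveExcitation(89.99, "TE", F))
    assert K0 * 0.999 < k89 < K0


def test_layer_kz_branch():
    # lossless oblique: real Pythagoras
    kz = layer_kz(1.0 + 0j, K0 / 2, F)
    assert kz == pytest.approx(K0 * np.sqrt(3) / 2, rel=1e-12)
    assert kz.imag == 0.0
    # lossy normal incidence: k0*sqrt(eps), fourth quadrant
    kz = layer_kz(8.5 - 9.9j, 0.0, F)
    assert kz / K0 == pytest.approx(SQRT_EPI, rel=1e-14)
    assert kz.imag < 0
    # evanescent lossless: decaying branch, not growing
    kz = layer_kz(1.0 + 0j, 2.0 * K0, F)
    assert kz.real == pytest.approx(0.0, abs=1e-6) and kz.imag < 0
    # grazing degenerate
    assert layer_kz(1.0 + 0j, K0, F) == 0.0


def test_wave_impedance_closed_forms():
    for pol in ("TE", "TM"):
        kz = layer_kz(1.0 + 0j, 0.0, F)
        z = wave_impedance(1.0 + 0j, kz, pol, F)
        assert abs(z - ETA0) < 0.01
    k_y = transverse_wavenumber(PlaneWaveExcitation(60.0, "TE", F))
    kz = layer_kz(1.0 + 0j, k_y, F)
    assert wave_impedance(1.0 + 0j, kz, "TE", F).real == pytest.approx(2 * ETA0, rel=1e-9)
    assert wave_impedance(1.0 + 0j, kz, "TM", F).real == pytest.approx(ETA0 / 2, rel=1e-9)
    with pytest.raises(DegenerateIncidenceError):
        wave_impedance(1.0 + 0j, 0.0, "TE", F)


def test_interface_reflection_matched_is_zero():
    assert interface_reflection(123.4 + 5j, 123.4 + 5j) == 0.0


def test_brewster_lossless_interface():
    """tan θB = sqrt(εr): TM reflection vanishes at 60° for εr = 3."""
    exc = PlaneWaveExcitation(60.0, "TM", F)
    k_y = transverse_wavenumber(exc)
    z_air = wave_impedance(1.0 + 0j, layer_kz(1.0 + 0j, k_y, F), "TM", F)
    z_diel = wave_impedance(3.0 + 0j, layer_kz(3.0 + 0j, k_y, F), "TM", F)
    assert abs(interface_reflection(z_diel, z_air)) < 1e-9


def test_quarter_wave_transformer_identity():
    eps1 = 4.0 + 0j
    lam1_mm = C0 / F / np.sqrt(eps1.real) * 1e3
    stack = StackRealization.from_layers(
        [("in", 1 + 0j, None), ("qw", eps1, lam1_mm / 4), ("load", 9.0 + 0j, None)],
        skin_interface=2)
    exc = PlaneWaveExcitation(0.0, "TE", F)
    zin = cascade_input_impedance(stack, exc)
    z1 = wave_impedance(eps1, layer_kz(eps1, 0.0, F), "TE", F)
    zl = wave_impedance(9.0 + 0j, layer_kz(9.0 + 0j, 0.0, F), "TE", F)
    assert zin[1] == pytest.approx(z1 ** 2 / zl, rel=1e-9)


def test_zero_thickness_layer_is_identity_transformer():
    base = StackRealization.from_layers(
        [("in", 1 + 0j, None), ("a", 3.0 - 1.0j, 0.7), ("t", 8.0 - 9.0j, None)], 2)
    padded = StackRealization.from_layers(
        [("in", 1 + 0j, None), ("ghost", 5.0 - 2.0j, 0.0), ("a", 3.0 - 1.0j, 0.7),
         ("t", 8.0 - 9.0j, None)], 3)
    exc = PlaneWaveExcitation(35.0, "TM", F)
    z1 = cascade_input_impedance(base, exc)
    z2 = cascade_input_impedance(padded, exc)
    assert z2[1] == pytest.approx(z1[1], rel=1e-12)


@pytest.mark.parametrize("trial", range(25))
def test_amplitudes_match_direct_boundary_solve(trial):
    """Cascade solution ≡ independent dense linear solve of the interface
    continuity conditions, on random lossy stacks at four angles and both
    polarizations (100 solves per trial batch)."""
    rng = np.random.default_rng(1000 + trial)
    stack = random_lossy_stack(rng, n_inner=int(rng.integers(2, 6)))
    for exc in excitations():
        sol = solve_fields(stack, exc)
        A, B = solve_fields_direct(stack, exc)
        for i in range(stack.n_layers):
            assert abs(complex(sol.A[i]) - A[i]) <= 1e-9 * abs(A[i])
            if 0 < abs(B[i]):
                assert abs(complex(sol.B[i]) - B[i]) <= 1e-9 * max(abs(B[i]), 1e-6 * abs(A[i]))


@pytest.mark.parametrize("trial", range(5))
def test_tangential_field_continuity(trial):
    rng = np.random.default_rng(50 + trial)
    stack = random_lossy_stack(rng)
    exc = PlaneWaveExcitation(float(rng.uniform(0, 85)), "TM" if trial % 2 else "TE")
    sol = solve_fields(stack, exc)
    z = 0.0
    for i in range(1, stack.n_layers):
        va, ia = sol.tangential_fields(z, side="above")
        vb, ib = sol.tangential_fields(z, side="below")
        assert abs(va - vb) <= 1e-9 * abs(va)
        assert abs(ia - ib) <= 1e-9 * abs(ia)
        if i < stack.n_layers - 1:
            z += stack.thickness_mm[i]


@pytest.mark.parametrize("trial", range(5))
def test_energy_conservation(trial):
    """IPD·cosθ0 = reflected flux + Σ per-layer absorption + termination flux."""
    rng = np.random.default_rng(200 + trial)
    stack = random_lossy_stack(rng)
    exc = PlaneWaveExcitation(float(rng.uniform(0, 80)), "TE" if trial % 2 else "TM")
    sol = solve_fields(stack, exc)
    inc = exc.incident_power_density * np.cos(np.radians(exc.theta0_deg))
    refl = 0.5 * abs(sol.B[0]) ** 2 * np.real(1.0 / np.conj(sol.Z[0]))
    absorbed = sum(sol.interface_flux(i) - sol.interface_flux(i + 1)
                   for i in range(1, stack.n_layers - 1))
    term = sol.interface_flux(stack.n_layers - 1)
    assert inc == pytest.approx(refl + absorbed + term, rel=1e-9)
    assert absorbed >= 0 and term >= 0


def test_lossless_gap_absorbs_nothing():
    stack = StackRealization.from_layers(
        [("in", 1 + 0j, None), ("cloth", 2.0 - 0.04j, 0.2), ("gap", 1 + 0j, 1.7),
         ("skin", 8.5 - 9.9j, None)], 3)
    sol = solve_fields(stack, PlaneWaveExcitation(33.0, "TM"))
    assert sol.interface_flux(2) == pytest.approx(sol.interface_flux(3), rel=1e-9)


def test_te_tm_degenerate_at_normal_incidence():
    stack = mean_bare_stack()
    s_te = solve_fields(stack, PlaneWaveExcitation(0.0, "TE"))
    s_tm = solve_fields(stack, PlaneWaveExcitation(0.0, "TM"))
    assert s_te.interface_flux(1) == pytest.approx(s_tm.interface_flux(1), rel=1e-12)
    r_te = abs(s_te.B[0] / s_te.A[0])
    r_tm = abs(s_tm.B[0] / s_tm.A[0])
    assert r_te == pytest.approx(r_tm, rel=1e-12)


@pytest.mark.parametrize("pol", ["TE", "TM"])
def test_fresnel_power_reflectance_closed_form(pol):
    """Single lossless interface matches the textbook Fresnel reflectance."""
    eps = 4.0
    n = np.sqrt(eps)
    for th in np.arange(0.0, 89.5, 1.0):
        stack = StackRealization.from_layers(
            [("in", 1 + 0j, None), ("d", eps + 0j, None)], 1)
        exc = PlaneWaveExcitation(float(th), pol)
        sol = solve_fields(stack, exc)
        got = abs(sol.B[0] / sol.A[0]) ** 2
        c1 = np.cos(np.radians(th))
        c2 = np.sqrt(1 - (np.sin(np.radians(th)) / n) ** 2)
        if pol == "TE":
            expect = ((c1 - n * c2) / (c1 + n * c2)) ** 2
        else:
            expect = ((n * c1 - c2) / (n * c1 + c2)) ** 2
        assert got == pytest.approx(expect, rel=1e-9, abs=1e-12)


def test_air_only_stack_is_transparent():
    stack = StackRealization.from_layers(
        [("in", 1 + 0j, None), ("slab", 1 + 0j, 2.5), ("out", 1 + 0j, None)], 2)
    exc = PlaneWaveExcitation(40.0, "TE")
    sol = solve_fields(stack, exc)
    inc = exc.incident_power_density * np.cos(np.radians(40.0))
    assert abs(sol.B[0]) < 1e-12 * abs(sol.A[0])
    assert sol.interface_flux(2) == pytest.approx(inc, rel=1e-12)


def test_incident_half_space_flux_bookkeeping():
    stack = mean_bare_stack()
    exc = PlaneWaveExcitation(25.0, "TM")
    sol = solve_fields(stack, exc)
    inc = exc.incident_power_density * np.cos(np.radians(25.0))
    refl = 0.5 * abs(sol.B[0]) ** 2 / sol.Z[0].real
    assert sol.poynting(-0.7) == pytest.approx(inc - refl, rel=1e-9)


def test_deep_muscle_flux_decays():
    """≥5 mm into muscle the flux is < 1e-3 of the skin-surface value, and the
    decay matches exp(2·Im(kz)·d)."""
    stack = mean_bare_stack()
    exc = PlaneWaveExcitation(0.0, "TE")
    sol = solve_fields(stack, exc)
    z3 = 0.0
    z_deep = float(np.sum([t for t in stack.thickness_mm[1:-1]])) + 5.0
    s3 = sol.poynting(z3, side="below")
    s_deep = sol.poynting(z_deep)
    assert s_deep < 1e-3 * s3
    kz_m = sol.kz[-1]
    s_top_muscle = sol.interface_flux(stack.n_layers - 1)
    expect = s_top_muscle * np.exp(2.0 * kz_m.imag * 5.0e-3)
    assert s_deep == pytest.approx(expect, rel=1e-9)


def test_muscle_termination_choice_is_immaterial():
    """Replacing the semi-infinite muscle with a finite slab over any backing
    changes the skin-surface flux by < 1e-6 relative."""
    reg_stack = mean_bare_stack()
    alt = StackRealization.from_layers(
        [("air", 1 + 0j, None),
         ("epidermis", 8.5 - 9.9j, 0.0794),
         ("dermis", 10.4 - 11.9j, 1.25),
         ("fat", 5.7 - 4.7j, 14.3),
         ("muscle", 10.7 - 13.9j, 14.4),
         ("backing", 1.0 + 0j, None)], 1)
    for exc in excitations(theta_list=(0.0, 55.0)):
        a = solve_fields(reg_stack, exc).interface_flux(1)
        b = solve_fields(alt, exc).interface_flux(1)
        assert abs(a - b) < 1e-6 * a


def test_exact_grazing_rejected():
    with pytest.raises(DegenerateIncidenceError):
        PlaneWaveExcitation(90.0, "TE")


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    theta=st.floats(0.0, 85.0),
    seed=st.integers(0, 10_000),
    pol=st.sampled_from(["TE", "TM"]),
)
def test_passivity_property(theta, seed, pol):
    """Random passive stacks never reflect or transmit more than incident."""
    rng = np.random.default_rng(seed)
    stack = random_lossy_stack(rng, n_inner=3)
    exc = PlaneWaveExcitation(theta, pol)
    sol = solve_fields(stack, exc)
    inc = exc.incident_power_density * np.cos(np.radians(theta))
    assert abs(sol.B[0] / sol.A[0]) <= 1.0 + 1e-12
    flux_in = sol.interface_flux(1)
    assert -1e-12 * inc <= flux_in <= inc * (1 + 1e-12)
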