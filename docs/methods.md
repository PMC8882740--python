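# Methods

## Physical model

The exposure scenario is a planar stratified medium: a semi-infinite air
half-space, one cloth layer, an air gap of controlled thickness `z_air`, and
the four-layer skin model (epidermis, dermis, subcutaneous fat, muscle), with
muscle treated as a semi-infinite termination. An infinite plane wave of
frequency 60 GHz arrives from the air side at incidence angle θ₀ ∈ [0°, 90°)
with either TE polarization (E perpendicular to the plane of incidence) or TM
(E parallel). The incident power density (IPD, default 26.6 W/m², the
reference level for local exposure of the general public at 60 GHz) is
defined on the plane normal to the wave vector, so the flux arriving per unit
area of body surface is IPD·cos θ₀.

Conventions: time factor e^{+jωt}, lossy permittivity ε = ε′ − jε″ with
ε″ ≥ 0, propagation e^{−jk·r}. Phase matching fixes the transverse
wavenumber k_y = k₀ sin θ₀ in every layer; the longitudinal wavenumber is
k_z = √(k₀²ε − k_y²) on the branch Im k_z ≤ 0 (decay into the body), with
Re k_z ≥ 0 in the lossless limit. Transverse wave impedances are
Z_TE = ωμ₀/k_z and Z_TM = k_z/(ωε₀ε). With the tangential-field pair
(V, I) ≡ (E_t, H_t) the normal Poynting flux is ½Re{V·I*} for both
polarizations, which makes the solver polarization-uniform.

### Solver

Interface continuity of V and I is solved by the amplitude form of the
per-layer 2×2 wave matrices: a bottom-up recursion propagates the reflection
coefficient Γ through each layer via Γ_top = Γ_bottom·e^{−2jk_z d}, then a
downward pass recovers forward/backward amplitudes in every layer. This form
only ever multiplies by e^{−2jk_z d}, whose magnitude is ≤ 1 in passive
layers, so it is stable for arbitrarily thick lossy layers (where the
tangent-form impedance recursion has poles and the raw transfer-matrix
product overflows). Backward amplitudes inside a layer are evaluated through
the bottom-referenced product B(ζ) = Γ_b·A·e^{−jk_z(2d−ζ)}, again with
non-growing exponents. The terminating half-space carries no backward wave by
construction.

An independent reference implementation (`mmwdosim.validation`) assembles
the full 2(L−1)-unknown linear system of continuity conditions and solves it
densely, with backward amplitudes referenced at layer bottoms so all matrix
entries stay bounded. The two paths agree to ~10⁻¹⁵ relative on random lossy
stacks; the test suite enforces 10⁻⁹ on 100+ stacks.

### Dosimetric quantities

* **APD** — net normal Poynting flux at the skin surface z₃ (the
  air-gap/epidermis boundary; z₃ = 0 for bare skin), in W/m².
* **Transmittance** — T = APD/(IPD·cos θ₀). For a bare stack this reduces
  exactly to 1 − |γ|² at the air/skin interface. We deliberately use this
  net-flux form rather than the literal local 1 − |γ₂|² with γ₂ the skin
  half-stack reflection coefficient: the local form depends only on the skin
  layers and the angle, so it cannot express any cloth or air-gap dependence
  and would force the clothed/bare ratio to 1 identically. The local form is
  still computed and exposed (`transmittance_local`, `gamma_skin`) for
  comparison.
* By construction APD = T·IPD·cos θ₀ everywhere (asserted to 10⁻¹²), hence
  clothed/bare APD ratios and transmittance ratios coincide cell by cell.
* **Normalized APD (dB)** — 10·log₁₀(mean APD / max mean APD), the maximum
  taken per material–polarization surface over the swept (θ₀ × z_air) grid,
  so each surface's peak cell is exactly 0 dB. A global maximum across
  materials would leave most surfaces unreachable from 0 dB.
* **Compliance** — mean APD ≤ 20 W/m² (basic restriction for local exposure
  of the general public), boundary inclusive since guideline limits are
  phrased as "should not exceed".

## Material parameters

The registry carries the published 60 GHz values: six cloths — cotton
(M1: ε = 2.0 − j0.04, 0.2 ± 0.02 mm), wool (M2: 1.22 − j0.036,
2.0 ± 0.02 mm), linen (M3: 1.25 − j0.102, 0.98 ± 0.1 mm), leatherette
(M4: 2.16 − j0.021, 0.91 ± 0.007 mm), polyester fiber (M5: 1.22 − j0.003,
0.79 ± 0.194 mm), latex mattress (M6: 1.11 − j0.009, 11.34 ± 0.241 mm) — and
the abdominal skin layers: epidermis (8.5 − j9.9, 0.0794 ± 0.0339 mm),
dermis (10.4 − j11.9, 1.25 ± 0.26 mm), fat (5.7 − j4.7, 14.3 ± 7.5 mm),
muscle (10.7 − j13.9, semi-infinite). Permittivity uncertainty is not
modeled (no published SDs). A custom registry can be supplied as YAML
(`--materials-file`).

Muscle is terminated semi-infinitely: at 60 GHz its field attenuation is
≈2.3 Np/mm, so any backing behind 14 mm of muscle changes the skin-surface
flux by < 10⁻⁶ relative (tested); the choice is numerically immaterial.

## Monte Carlo design

* Thicknesses are independent Normal(mean, SD) draws per layer, truncated to
  strictly positive values by rejection resampling. Rejection preserves the
  conditional normal shape and is reproducible. The induced mean shift is
  ≈ +1.1% for the epidermis (P(X ≤ 0) ≈ 1%) and ≈ +3.5% for fat
  (P ≈ 2.8%); other layers are unaffected to < 0.1%. Tests compare sample
  moments against `scipy.stats.truncnorm` for this reason.
* The air gap is a controlled sweep variable (grid default 0–5 mm, step
  0.1 mm, resolving the 2.5 mm half-wavelength periodicity), never sampled.
* 10⁴ draws per cell (study condition); the default angle grid is 0–80° in
  1° steps. At these settings the full 6-material, 2-polarization sweep
  (≈49 000 cells, ≈5×10⁸ stack evaluations) runs in about two minutes on one
  CPU because the solver is vectorized over draws × air-gap grid.
* **Pairing (common random numbers)**: the bare-skin reference reuses the
  identical skin-layer draws of the clothed evaluation. Skin draws are keyed
  by (master seed, θ-index) and cloth draws by (master seed, material-index,
  θ-index) through `numpy.random.SeedSequence` spawn keys, and are shared
  across air-gap values and polarizations. Consequences: the bare reference
  is identical for every material and air gap at a given angle; air-gap
  fluctuation curves carry no draw-to-draw Monte Carlo noise; sweeps are
  bit-reproducible regardless of cell evaluation order. Ratios are computed
  as mean/mean, not mean-of-ratios.
* Relative SD ≡ 100·SD/mean, with SD forced to exactly 0 when all draws in
  a cell are identical (degenerate, all-SDs-zero configurations).
* The Brewster statistic is the argmax over θ₀ of the mean-transmittance
  curve, refined by quadratic interpolation through the grid maximum and its
  neighbours; an edge maximum (e.g. monotone TE profiles peaking at 0°) is
  flagged as a boundary rather than interpolated.

## What the generator emulates — and what it does not

The synthetic thickness draws reproduce the study's stated stochastic
structure: independent, normally distributed layer thicknesses with the
published means and SDs, truncated positive. They do not model correlation
between layers, permittivity uncertainty, layer roughness or curvature,
finite beams, or spatial averaging of power density over evaluation areas.
Passing tests therefore demonstrate correctness of the stratified-media
solver and of the statistics pipeline under the planar, plane-wave,
independent-thickness assumptions — not fidelity to anatomically realistic
3-D exposure.

## Numerical choices

* Grazing guard: θ₀ = 90° is rejected; wave impedances raise on exact
  k_z = 0. Sweep grids stop at ≤ 85°.
* Zero-thickness layers are exact identity transformers (e^{0} = 1), so a
  closed air gap (z_air = 0) needs no special casing; a vacuum cloth with
  zero gap reproduces bare-skin results to 10⁻¹² relative (bitwise equality
  is impossible because the extra unit-modulus phase factors round
  differently).
* Tie-breaks: the quadratic Brewster refinement falls back to the grid node
  when the three-point curvature vanishes.
* All external thickness I/O is in millimetres; SI units internally; power
  densities in W/m².

## Known limitations and divergences from the source study

Several statistics reported by the source study are not reproduced by this
standard phase-matched formulation, and the discrepancies are internally
consistent with each other:

1. Because APD = T·IPD·cos θ₀, the clothed/bare APD ratio equals the
   transmittance ratio at the same cell. The source reports a transmittance
   ratio > 2.3 *and* an APD ratio < 0.8 for the same configuration
   (leatherette, TE, 60°, 2.5 mm gap) — mutually incompatible under any
   flux-consistent definition. Our model reproduces the APD side (0.76 max
   across cloths at that cell set; the leatherette cell itself is 0.22).
2. Our model does produce the reported > 0.9 steep-angle TE transmittance
   for leatherette-clad skin, but at air gaps displaced by half a
   gap-resonance period from where the source places them (peak near
   z_air ≈ 0.1 mm at 75°, ≈ 5 mm at 60°, rather than inside the 2.5–5 mm
   band). At normal incidence, where the gap phase is convention-free, our
   resonance positions and ratio maxima (1.36 at 2.5 mm vs the reported 1.4)
   agree. The displacement pattern is what one obtains if the gap phase is
   accumulated along the slant path (k₀·z/cos θ) instead of the
   phase-matched k₀·z·cos θ; we implement the standard form.
3. The leatherette layer is a quarter-wave transformer near 32° TM
   (k_z·d ≈ π/2), so for some air gaps (0 and 5 mm) the low-angle TM
   transmittance maximum genuinely exceeds the Brewster peak; the
   maximum-transmittance angle then falls far below the reported 60–80°
   window (which all other cloth/gap cells do respect, topping out at 76.5°).
4. The per-surface normalized APD cannot stay within −1 dB for θ₀ < 40°:
   the obliquity factor alone contributes cos 39° ≙ −1.1 dB, and the
   leatherette gap resonance adds dips to ≈ −7 dB.
5. At the 26.6 W/m² reference level, the leatherette half-wave-gap resonance
   pushes the mean APD to ≈ 23 W/m² near normal incidence, above the 20 W/m²
   basic restriction — a direct consequence of the 1.36× enhancement acting
   on the 16.2 W/m² bare-skin APD. The corresponding test states the
   guideline claim and is expected to fail under this model.

These cases are asserted at face value in the acceptance tests so the
disagreement stays visible rather than being tuned away.
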