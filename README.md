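# mmwdosim

Monte Carlo dosimetry of **clothed human skin exposed to oblique plane waves
at 60 GHz**.

Millimeter-wave exposure guidelines (ICNIRP 2020, IEEE C95.1-2019) limit the
*absorbed power density* (APD) — the time-averaged power flux crossing a unit
area of the skin surface in the normal direction — to 20 W/m² for local
exposure of the general public above 6 GHz. Real exposures happen through
clothing: a textile layer and the air gap behind it act as an impedance
transformer that can raise or lower the power delivered to the skin, and the
effect depends on incidence angle and polarization. `mmwdosim` quantifies
this for a planar stack

```
air | cloth | air gap (z_air) | epidermis | dermis | fat | muscle
```

with published 60 GHz complex permittivities and thickness statistics for six
textiles (cotton, wool, linen, leatherette, polyester fiber, latex) and the
four-layer abdominal skin model.

## Model

A TE- or TM-polarized plane wave is incident from air at angle θ₀ with
incident power density *IPD* (26.6 W/m² by default, the 60 GHz reference
level) defined on the wave-normal plane. Each layer i carries forward and
backward waves with longitudinal wavenumber

> k_z,i = √(k₀² ε_i − k_y²),  k_y = k₀ sin θ₀,  Im k_z ≤ 0,

under the e^{+jωt} convention with ε = ε′ − jε″. Tangential-field continuity
at every interface is solved by a stable amplitude-ratio cascade (the 2×2
wave-matrix recursion). The two dosimetric outputs at the skin surface z₃
(air-gap/epidermis boundary) are

> APD = ½ Re{(E × H*) · n}|_{z₃},  T = APD / (IPD·cos θ₀).

Layer thicknesses are random: independent normal draws with the published
mean ± SD, truncated to positive values, 10⁴ draws per (material,
polarization, θ₀, z_air) cell, with the bare-skin reference sharing the same
skin draws (common random numbers). The sweep reports per-cell means, SDs,
relative SDs, clothed/bare ratios, Brewster (maximum-transmittance) angles,
air-gap fluctuation depth in dB, and compliance against the 20 W/m² basic
restriction.

## Worked example

```python
from mmwdosim import SweepConfig, run_sweep
from mmwdosim import dosimetry

cfg = SweepConfig(materials=("M4",), polarizations=("TE",),
                  theta0_deg=(0.0,), z_air_mm=(2.5,),
                  n_iterations=10_000, seed=1)
row = run_sweep(cfg).data.iloc[0]
print(f"bare skin:    T = {row.bare_t_mean:.3f}   APD = {row.bare_apd_mean_wm2:.2f} W/m^2")
print(f"M4, 2.5 mm:   T = {row.t_mean:.3f}   APD = {row.apd_mean_wm2:.2f} +/- {row.apd_sd_wm2:.2f} W/m^2")
print(f"clothed/bare APD ratio = {row.apd_ratio:.2f}")
res = dosimetry.compliance_check(row.apd_mean_wm2)
print(f"basic restriction 20 W/m^2: {'PASS' if res.passed else 'EXCEEDED'} "
      f"(margin {res.margin_wm2:.2f} W/m^2)")
```

prints

```
bare skin:    T = 0.608   APD = 16.17 W/m^2
M4, 2.5 mm:   T = 0.827   APD = 21.99 +/- 0.10 W/m^2
clothed/bare APD ratio = 1.36
basic restriction 20 W/m^2: EXCEEDED (margin -1.99 W/m^2)
```

Bare skin at normal incidence absorbs 61% of the incident flux. Adding a
0.91 mm leatherette layer 2.5 mm (half a free-space wavelength) in front of
the skin forms a resonant transformer that raises the mean APD by 36% — at
this reference-level IPD the mean APD then slightly exceeds the 20 W/m² basic
restriction. The ±0.10 W/m² Monte Carlo SD shows the thickness variability of
cloth and skin barely perturbs the result at normal incidence.

The same study can be run from the shell:

```sh
mmwdosim run --materials M4 --pol TE --theta 0:80:1 --zair 0:5:0.1 --seed 1 --out out/
mmwdosim report  --summary out/sweep.csv
mmwdosim surface --summary out/sweep.csv --quantity APD_db --material M4 --pol TE --out m4_te_db.csv
```

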