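# Full default study: six cloths, both polarizations, 60 GHz, IPD 26.6 W/m².
# Run with:  mmwdosim run --config examples/study.yaml --out out/
materials: [M1, M2, M3, M4, M5, M6]
polarizations: [TE, TM]
theta0_deg: "0:80:1"      # degrees, start:stop:step (stop inclusive)
z_air_mm: "0:5:0.1"       # air gap between cloth and skin, mm
n_iterations: 10000       # Monte Carlo thickness draws per cell
seed: 1
frequency_hz: 60.0e9
incident_power_density: 26.6
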