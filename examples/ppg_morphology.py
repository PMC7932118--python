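"""Synthesize the peripheral pulse (PPG) and compare disease morphologies.

The PPG is modelled as (k1 P_sa - k2 P_ra)/R_s: forward arterial inflow
minus venous return, unit-free. Valve disease flattens the pulse: both
stenosis (less output) and regurgitation (lower pressure) reduce the
systolic amplitude relative to the healthy trace.
"""

from cvloop.runner import RunConfiguration, run_scenario

runs = {
    "healthy": RunConfiguration(),
    "MS very severe": RunConfiguration(mitral_resistance_ratio=50.0),
    "MR severe": RunConfiguration(delta_mi=0.05),
}
for tag, cfg in runs.items():
    f = run_scenario(cfg).ppg_features[0]
    notch = f"{f.notch_time:.3f} s" if f.notch_time is not None else "absent"
    dia = f"{f.diastolic_relative:.2f}" if f.diastolic_relative is not None else "absent"
    print(f"{tag:>15}: systolic amplitude {f.systolic_amplitude:6.1f}  "
          f"notch {notch:>8}  diastolic/systolic {dia}")
print("\nAmplitudes are unit-free; only their relative change across conditions matters.")
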