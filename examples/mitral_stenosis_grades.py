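"""Sweep mitral stenosis severity and watch the hemodynamics deteriorate.

Stenosis narrows the mitral orifice; the model raises the trans-mitral
resistance by the grade ratio (mild 5x, severe 15x, very severe 50x over
healthy). Expect cardiac output, ejection fraction and arterial pressure to
fall while the left atrium dilates.
"""

from cvloop.disease import MS_GRADE_RATIOS
from cvloop.runner import RunConfiguration, run_scenario

print(f"{'grade':>12} {'CO L/min':>9} {'EF %':>6} {'MAP mmHg':>9} {'LAEDD cm':>9}")
healthy = run_scenario(RunConfiguration()).indices
print(f"{'healthy':>12} {healthy.CO:9.2f} {healthy.EF:6.1f} {healthy.MAP:9.1f} {healthy.LAEDD:9.2f}")
for grade, ratio in MS_GRADE_RATIOS.items():
    idx = run_scenario(RunConfiguration(mitral_resistance_ratio=ratio)).indices
    print(f"{grade:>12} {idx.CO:9.2f} {idx.EF:6.1f} {idx.MAP:9.1f} {idx.LAEDD:9.2f}")
print("\nCO/EF/MAP fall and the left atrium enlarges monotonically with severity.")
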