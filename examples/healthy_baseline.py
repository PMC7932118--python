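"""Simulate a healthy adult at rest and print the standard cardiac indices.

Runs the calibrated closed-loop profile driven by a 75 bpm ECG template
until the pressure-volume loop settles onto its limit cycle, then reports
the indices a clinician would read off an echo/catheter study.
"""

from cvloop.runner import RunConfiguration, run_scenario

scenario = run_scenario(RunConfiguration())
idx = scenario.indices

print(f"converged after {scenario.result.steady_state_cycle_index} cycles "
      f"({scenario.result.steady_state_cycle_index * scenario.result.timing[0].T:.1f} s simulated)")
print(f"EDV  {idx.EDV:7.1f} mL   end-diastolic lv volume (preload)")
print(f"ESV  {idx.ESV:7.1f} mL   end-systolic lv volume (residual)")
print(f"SV   {idx.SV:7.1f} mL   stroke volume = EDV - ESV")
print(f"CO   {idx.CO:7.2f} L/min cardiac output = forward SV x HR")
print(f"EF   {idx.EF:7.1f} %    ejection fraction (healthy: ~55-60%)")
print(f"MAP  {idx.MAP:7.1f} mmHg mean systemic arterial pressure")
print(f"LVEDD{idx.LVEDD:7.2f} cm   lv end-diastolic diameter (ellipsoid model)")
print(f"LAEDD{idx.LAEDD:7.2f} cm   la diameter at lv end-diastole")
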