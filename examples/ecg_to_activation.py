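"""From a single-lead ECG to the activation timing that drives the heart.

Synthesizes a 75 bpm PQRST template, detects the per-cycle fiducials, and
converts them to the activation-timing parameters of the compliance model:
T_a (atrial onset), d_la (left-atrial delay), d (ventricular delay),
T1/T2 (systolic/diastolic instants) and T (cycle length).
"""

from cvloop.ecg import activation_from_fiducials, detect_fiducials, synthesize_ecg

ecg = synthesize_ecg(heart_rate_bpm=75.0, n_cycles=6)
cycles = detect_fiducials(ecg)
print(f"detected {len(cycles)} complete cycles from {ecg.duration:.1f} s of ECG")

f = cycles[0]
print(f"fiducials (s into cycle): P={f.t_P:.3f} Q={f.t_Q:.3f} R={f.t_R:.3f} "
      f"S={f.t_S:.3f} T={f.t_T:.3f}  cycle length {f.cycle_length:.3f}")

a = activation_from_fiducials(f)
print(f"activation timing: T_a={a.T_a:.3f} d_la={a.d_la:.3f} d={a.d:.3f} "
      f"T1={a.T1:.3f} T2={a.T2:.3f} T={a.T:.3f}")
print("\nT_a marks the atrial kick onset; d is the atrioventricular conduction")
print("delay; the ventricular compliance bottoms out (peak contraction) at d + T1.")
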