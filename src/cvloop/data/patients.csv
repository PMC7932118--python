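patient_id,leadII_p_peak_separation,leadII_p_duration,leadV1_p_terminal_neg_duration,leadV1_p_terminal_neg_amplitude,leadI_R_amp,leadIII_S_amp,leadV1_S_amp,leadV2_S_amp,leadV5_R_amp,leadV6_R_amp,stt_opposite_qrs_without_digitalis,stt_opposite_qrs_with_digitalis,left_atrial_enlargement_present,qrs_duration,leadV5_intrinsicoid,leadV6_intrinsicoid
107,45,121,67,1.0,5,5,5,4.8,5,5,no,yes,yes,75,35,42
110,101,155,76,1.25,12,19,35,32,25,29,yes,no,yes,115,55,49
188,78,147,70,1.0,17.5,10.5,37,34,45,42,yes,no,yes,125,50,50
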