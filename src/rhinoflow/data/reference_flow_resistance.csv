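# Per-subject flow partition and nasal-resistance values of the eight-subject
# reference septoturbinoplasty cohort, pre- and postoperative models solved at
# the matched trans-nasal pressure drop.  MOS = more obstructed side (labeled
# preoperatively).  Partition in percent of total nostril flow; resistances in
# Pa/(mL*s): unilateral between nostril and choanae, bilateral between the
# inlet chamber and the choanae.
subject,state,flow_partition_mos_pct,partition_ratio_los_over_mos,nr_unilateral_mos_Pa_per_mL_s,nr_ratio_mos_over_los,nr_bilateral_Pa_per_mL_s
S1,PREOP,20.2,3.95,0.312,5.24,0.0680
S1,POSTOP,40.8,1.45,0.055,1.85,0.0321
S2,PREOP,21.5,3.65,0.299,4.36,0.0663
S2,POSTOP,43.2,1.31,0.061,1.59,0.0326
S3,PREOP,19.8,4.05,0.299,6.82,0.0616
S3,POSTOP,41.2,1.43,0.091,1.91,0.0459
S4,PREOP,44.1,1.27,0.074,1.32,0.0350
S4,POSTOP,44.6,1.24,0.010,1.71,0.0098
S5,PREOP,39.8,1.51,0.211,1.90,0.0973
S5,POSTOP,30.2,2.31,0.189,5.04,0.0661
S6,PREOP,43.1,1.32,0.151,1.36,0.0681
S6,POSTOP,43.5,1.30,0.029,1.66,0.0188
S7,PREOP,34.4,1.91,0.053,3.69,0.0237
S7,POSTOP,46.9,1.13,0.007,1.42,0.0156
S8,PREOP,29.8,2.36,0.204,4.95,0.0689
S8,POSTOP,44.6,1.24,0.087,1.55,0.0512
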