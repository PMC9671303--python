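# Printed summary statistics of the reference septoturbinoplasty study, kept
# for regression checks and context.  'decimals' is the printed precision.
# recomputable=True rows can be re-derived from the per-subject fixtures;
# recomputable=False rows (plane relative humidity / air temperature) depend
# on the study's 3-D CFD fields and are reference-only.
variable,state,statistic,value,decimals,recomputable
nose,PREOP,mean,14.4,1,True
nose,PREOP,sd_sample,3.9,1,True
nose,PREOP,sd_population,3.6,1,True
nose,POSTOP,mean,4.0,1,True
nose,POSTOP,sd_sample,4.5,1,True
nose,POSTOP,sd_population,4.2,1,True
nose_improvement,CHANGE,mean,10.4,1,True
nose_improvement,CHANGE,sd_sample,4.8,1,True
nose_improvement_good_response,CHANGE,mean,15.7,1,True
nose_improvement_good_response,CHANGE,sd_sample,2.1,1,True
nose_improvement_other,CHANGE,mean,7.2,1,True
nose_improvement_other,CHANGE,sd_sample,2.3,1,True
flow_partition_mos_pct,PREOP,mean,31.6,1,True
flow_partition_mos_pct,PREOP,sd_sample,10.3,1,True
flow_partition_mos_pct,PREOP,sd_population,9.6,1,True
flow_partition_mos_pct,POSTOP,mean,41.9,1,True
flow_partition_mos_pct,POSTOP,sd_sample,5.1,1,True
flow_partition_mos_pct,POSTOP,sd_population,4.7,1,True
partition_ratio_los_over_mos,PREOP,mean,2.50,2,True
partition_ratio_los_over_mos,PREOP,sd_sample,1.20,2,True
partition_ratio_los_over_mos,POSTOP,mean,1.43,2,True
partition_ratio_los_over_mos,POSTOP,sd_sample,0.37,2,True
nr_unilateral_mos_Pa_per_mL_s,PREOP,mean,0.200,3,True
nr_unilateral_mos_Pa_per_mL_s,PREOP,sd_sample,0.101,3,True
nr_unilateral_mos_Pa_per_mL_s,PREOP,sd_population,0.095,3,True
nr_unilateral_mos_Pa_per_mL_s,POSTOP,mean,0.066,3,True
nr_unilateral_mos_Pa_per_mL_s,POSTOP,sd_sample,0.059,3,True
nr_unilateral_mos_Pa_per_mL_s,POSTOP,sd_population,0.055,3,True
nr_unilateral_los_Pa_per_mL_s,PREOP,mean,0.063,3,True
nr_unilateral_los_Pa_per_mL_s,PREOP,sd_sample,0.034,3,True
nr_unilateral_los_Pa_per_mL_s,POSTOP,mean,0.030,3,True
nr_unilateral_los_Pa_per_mL_s,POSTOP,sd_sample,0.018,3,True
nr_bilateral_Pa_per_mL_s,PREOP,mean,0.061,3,True
nr_bilateral_Pa_per_mL_s,PREOP,sd_sample,0.023,3,True
nr_bilateral_Pa_per_mL_s,POSTOP,mean,0.034,3,True
nr_bilateral_Pa_per_mL_s,POSTOP,sd_sample,0.019,3,True
nr_bilateral_reduction_Pa_per_mL_s,CHANGE,mean,0.027,3,True
nr_bilateral_reduction_Pa_per_mL_s,CHANGE,sd_population,0.012,3,True
nr_ratio_mos_over_los,PREOP,mean,3.71,2,True
nr_ratio_mos_over_los,PREOP,sd_sample,2.02,2,True
nr_ratio_mos_over_los,POSTOP,mean,2.09,2,True
nr_ratio_mos_over_los,POSTOP,sd_sample,1.20,2,True
plane1_mos_RH_pct,PREOP,mean,98.6,1,False
plane1_los_RH_pct,PREOP,mean,93.4,1,False
plane2_RH_pct,PREOP,mean,94.9,1,False
plane1_mos_RH_pct,POSTOP,mean,89.3,1,False
plane1_los_RH_pct,POSTOP,mean,83.5,1,False
plane2_RH_pct,POSTOP,mean,86.2,1,False
plane1_mos_T_C,PREOP,mean,33.1,1,False
plane1_los_T_C,PREOP,mean,31.9,1,False
plane2_T_C,PREOP,mean,32.3,1,False
plane1_mos_T_C,POSTOP,mean,31.5,1,False
plane1_los_T_C,POSTOP,mean,30.7,1,False
plane2_T_C,POSTOP,mean,31.0,1,False
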