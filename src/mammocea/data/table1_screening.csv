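parameter,arm,value,dist,alpha,beta,sd
double_read_share,aidm,0.3,fixed,,,
double_read_share,cdm,1.0,fixed,,,
conference_prop,aidm,0.04,beta,1475,35403,
conference_prop,cdm,0.039,beta,1404,34590,
recall_prop_40_54,both,0.035,beta,4541,125208,
recall_prop_55_74,both,0.025,beta,2341,91297,
detect_biennial_overall,aidm,0.0061,beta,222,36169,
detect_biennial_overall,cdm,0.0051,beta,203,39576,
detect_biennial_40_54,aidm,0.0032,derived,,,
detect_biennial_40_54,cdm,0.0027,derived,,,
detect_biennial_55_74,aidm,0.0086,printed,,,
detect_biennial_55_74,cdm,0.0072,printed,,,
interval_annual_40_54,aidm,0.0003,derived,,,
interval_annual_40_54,cdm,0.0006,derived,,,
interval_annual_55_74,aidm,0.0008,derived,,,
interval_annual_55_74,cdm,0.0015,derived,,,
age_factor_40_54,both,0.53,fixed,,,
age_factor_55_74,both,1.4,fixed,,,
interval_share,both,0.295,fixed,,,
cost_invitation,both,0.7,fixed,,,
cost_mammography,both,30.5,fixed,,,
reads_per_hour,both,29,fixed,,,
cost_radiologist_hour,both,79.0,fixed,,,
cost_screen_reading,both,2.7,gamma,,,0.5
cost_ai_licence,both,1.9,fixed,,,
cost_conference,both,5.4,gamma,,,1.1
cost_recall,both,370.8,fixed,,,
cost_external_reading,both,4.8,fixed,,,
discount_rate,both,0.03,fixed,,,
wtp_threshold,both,50000,fixed,,,
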