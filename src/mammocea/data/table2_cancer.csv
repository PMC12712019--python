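block,key,stage,year,value
stage_dist,screening:40_54,0,,0.22
stage_dist,screening:40_54,I,,0.48
stage_dist,screening:40_54,II,,0.21
stage_dist,screening:40_54,III,,0.086
stage_dist,screening:40_54,IV,,0.004
stage_dist,interval:40_54,0,,0.073
stage_dist,interval:40_54,I,,0.393
stage_dist,interval:40_54,II,,0.301
stage_dist,interval:40_54,III,,0.194
stage_dist,interval:40_54,IV,,0.04
stage_dist,screening:55_74,0,,0.143
stage_dist,screening:55_74,I,,0.624
stage_dist,screening:55_74,II,,0.173
stage_dist,screening:55_74,III,,0.056
stage_dist,screening:55_74,IV,,0.005
stage_dist,interval:55_74,0,,0.065
stage_dist,interval:55_74,I,,0.408
stage_dist,interval:55_74,II,,0.295
stage_dist,interval:55_74,III,,0.167
stage_dist,interval:55_74,IV,,0.065
stage_dist,post75:75plus,0,,0.047
stage_dist,post75:75plus,I,,0.341
stage_dist,post75:75plus,II,,0.384
stage_dist,post75:75plus,III,,0.163
stage_dist,post75:75plus,IV,,0.065
metastasis_risk,,0,1,0.0
metastasis_risk,,0,2,0.0
metastasis_risk,,0,3,0.0
metastasis_risk,,0,4,0.0
metastasis_risk,,0,5,0.0
metastasis_risk,,0,6,0.0
metastasis_risk,,0,7,0.0
metastasis_risk,,0,8,0.0
metastasis_risk,,0,9,0.0
metastasis_risk,,I,1,0.001
metastasis_risk,,I,2,0.004
metastasis_risk,,I,3,0.004
metastasis_risk,,I,4,0.004
metastasis_risk,,I,5,0.005
metastasis_risk,,I,6,0.005
metastasis_risk,,I,7,0.005
metastasis_risk,,I,8,0.005
metastasis_risk,,I,9,0.005
metastasis_risk,,II,1,0.01
metastasis_risk,,II,2,0.018
metastasis_risk,,II,3,0.019
metastasis_risk,,II,4,0.019
metastasis_risk,,II,5,0.016
metastasis_risk,,II,6,0.016
metastasis_risk,,II,7,0.016
metastasis_risk,,II,8,0.016
metastasis_risk,,II,9,0.016
metastasis_risk,,III,1,0.025
metastasis_risk,,III,2,0.076
metastasis_risk,,III,3,0.071
metastasis_risk,,III,4,0.059
metastasis_risk,,III,5,0.033
metastasis_risk,,III,6,0.028
metastasis_risk,,III,7,0.021
metastasis_risk,,III,8,0.02
metastasis_risk,,III,9,0.019
bc_death_risk,,IV,1,0.368
bc_death_risk,,IV,2,0.324
bc_death_risk,,IV,3,0.307
bc_death_risk,,IV,4,0.339
bc_death_risk,,IV,5,0.249
bc_death_risk,,IV,6,0.068
bc_death_risk,,IV,7,0.039
bc_death_risk,,IV,8,0.039
bc_death_risk,,IV,9,0.039
cost,,0,1,12652
cost,,0,2,0
cost,,0,3,0
cost,,0,4,0
cost,,0,5,0
cost,,0,6,0
cost,,0,7,0
cost,,0,8,0
cost,,0,9,0
cost,,I,1,12652
cost,,I,2,3489
cost,,I,3,3489
cost,,I,4,3489
cost,,I,5,3489
cost,,I,6,3489
cost,,I,7,3489
cost,,I,8,3489
cost,,I,9,3489
cost,,II,1,12652
cost,,II,2,3489
cost,,II,3,3489
cost,,II,4,3489
cost,,II,5,3489
cost,,II,6,3489
cost,,II,7,3489
cost,,II,8,3489
cost,,II,9,3489
cost,,III,1,12652
cost,,III,2,3489
cost,,III,3,3489
cost,,III,4,3489
cost,,III,5,3489
cost,,III,6,3489
cost,,III,7,3489
cost,,III,8,3489
cost,,III,9,3489
cost,,IV,1,22752
cost,,IV,2,22752
cost,,IV,3,22752
cost,,IV,4,22752
cost,,IV,5,22752
cost,,IV,6,22752
cost,,IV,7,22752
cost,,IV,8,22752
cost,,IV,9,22752
qol_decrement,,0,1,0.018
qol_decrement,,0,2,0
qol_decrement,,0,3,0
qol_decrement,,0,4,0
qol_decrement,,0,5,0
qol_decrement,,0,6,0
qol_decrement,,0,7,0
qol_decrement,,0,8,0
qol_decrement,,0,9,0
qol_decrement,,I,1,0.018
qol_decrement,,I,2,0.018
qol_decrement,,I,3,0.018
qol_decrement,,I,4,0.018
qol_decrement,,I,5,0.018
qol_decrement,,I,6,0.018
qol_decrement,,I,7,0.018
qol_decrement,,I,8,0.018
qol_decrement,,I,9,0.018
qol_decrement,,II,1,0.018
qol_decrement,,II,2,0.018
qol_decrement,,II,3,0.018
qol_decrement,,II,4,0.018
qol_decrement,,II,5,0.018
qol_decrement,,II,6,0.018
qol_decrement,,II,7,0.018
qol_decrement,,II,8,0.018
qol_decrement,,II,9,0.018
qol_decrement,,III,1,0.077
qol_decrement,,III,2,0.077
qol_decrement,,III,3,0.077
qol_decrement,,III,4,0.077
qol_decrement,,III,5,0.077
qol_decrement,,III,6,0.077
qol_decrement,,III,7,0.077
qol_decrement,,III,8,0.077
qol_decrement,,III,9,0.077
qol_decrement,,IV,1,0.099
qol_decrement,,IV,2,0.099
qol_decrement,,IV,3,0.099
qol_decrement,,IV,4,0.099
qol_decrement,,IV,5,0.099
qol_decrement,,IV,6,0.099
qol_decrement,,IV,7,0.099
qol_decrement,,IV,8,0.099
qol_decrement,,IV,9,0.099
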