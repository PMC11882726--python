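trait_a,trait_b,value,se
UKB_Trails,UKB_Trails,0.1141,0.0082
UKB_Trails,UKB_Pairs,0.7097,0.0445
UKB_Trails,UKB_SDST,0.7133,0.0466
UKB_Trails,UKB_Digit,0.6685,0.047
UKB_Trails,UKB_PMemory,0.3358,0.0569
UKB_Trails,CHARGE_DSST,0.5832,0.0663
UKB_Trails,CHARGE_Stroop,0.3873,0.1108
UKB_Trails,ALSPAC_WM,0.4237,0.1151
UKB_Trails,StopSignal,-0.1003,0.1235
UKB_Trails,NIH_G6,0.9472,0.1063
UKB_Trails,NIH_G4,0.6379,0.0794
UKB_Pairs,UKB_Pairs,0.3765,0.0163
UKB_Pairs,UKB_SDST,0.6571,0.0409
UKB_Pairs,UKB_Digit,0.439,0.0339
UKB_Pairs,UKB_PMemory,0.3331,0.0461
UKB_Pairs,CHARGE_DSST,0.5568,0.0559
UKB_Pairs,CHARGE_Stroop,0.2358,0.0772
UKB_Pairs,ALSPAC_WM,0.324,0.0789
UKB_Pairs,StopSignal,0.0614,0.0945
UKB_Pairs,NIH_G6,0.8126,0.0872
UKB_Pairs,NIH_G4,0.534,0.0561
UKB_SDST,UKB_SDST,0.1564,0.0094
UKB_SDST,UKB_Digit,0.3224,0.0442
UKB_SDST,UKB_PMemory,0.2257,0.0506
UKB_SDST,CHARGE_DSST,0.8745,0.0717
UKB_SDST,CHARGE_Stroop,0.3596,0.0986
UKB_SDST,ALSPAC_WM,0.3136,0.1125
UKB_SDST,StopSignal,0.2078,0.1232
UKB_SDST,NIH_G6,1.0443,0.0999
UKB_SDST,NIH_G4,0.4092,0.0717
UKB_Digit,UKB_Digit,0.1433,0.0091
UKB_Digit,UKB_PMemory,0.2328,0.0514
UKB_Digit,CHARGE_DSST,0.3836,0.0605
UKB_Digit,CHARGE_Stroop,0.4496,0.1077
UKB_Digit,ALSPAC_WM,0.6427,0.109
UKB_Digit,StopSignal,-0.0349,0.1317
UKB_Digit,NIH_G6,0.629,0.1062
UKB_Digit,NIH_G4,0.606,0.0724
UKB_PMemory,UKB_PMemory,0.0368,0.0035
UKB_PMemory,CHARGE_DSST,0.3206,0.077
UKB_PMemory,CHARGE_Stroop,0.2728,0.1326
UKB_PMemory,ALSPAC_WM,0.4875,0.1459
UKB_PMemory,StopSignal,0.1959,0.1684
UKB_PMemory,NIH_G6,0.5353,0.1385
UKB_PMemory,NIH_G4,0.6067,0.0907
CHARGE_DSST,CHARGE_DSST,0.156,0.0178
CHARGE_DSST,CHARGE_Stroop,0.5018,0.1355
CHARGE_DSST,ALSPAC_WM,0.3977,0.1579
CHARGE_DSST,StopSignal,0.4738,0.173
CHARGE_DSST,NIH_G6,1.1107,0.1533
CHARGE_DSST,NIH_G4,0.3564,0.1022
CHARGE_Stroop,CHARGE_Stroop,0.1035,0.0336
CHARGE_Stroop,ALSPAC_WM,-0.2293,0.2989
CHARGE_Stroop,StopSignal,-0.3916,0.301
CHARGE_Stroop,NIH_G6,0.0503,0.2526
CHARGE_Stroop,NIH_G4,0.2171,0.1597
ALSPAC_WM,ALSPAC_WM,0.279,0.1097
ALSPAC_WM,StopSignal,0.5458,0.3198
ALSPAC_WM,NIH_G6,0.675,0.2609
ALSPAC_WM,NIH_G4,0.4308,0.1842
StopSignal,StopSignal,0.0489,0.0272
StopSignal,NIH_G6,0.0534,0.2997
StopSignal,NIH_G4,-0.2009,0.2166
NIH_G6,NIH_G6,0.1388,0.0552
NIH_G6,NIH_G4,0.6175,0.2003
NIH_G4,NIH_G4,0.3436,0.0597
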