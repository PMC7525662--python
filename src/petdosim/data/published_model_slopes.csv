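radiotracer,phantom,normalised,reconstruction,r2,printed_bias_pct,slope,sem,ci_low,ci_high
FDG,adult_male,False,FBP,0.754,111.1,2.111,0.1083,1.898,2.323
FDG,adult_male,True,FBP,0.855,40.44,0.5956,0.02207,0.5523,0.6388
FDG,adult_male,False,iterative,0.786,274.2,3.742,0.1752,3.398,4.085
FDG,adult_male,True,iterative,0.865,11.26,1.126,0.03988,1.047,1.204
FDG,adult_female,False,FBP,0.751,194.1,2.941,0.1486,2.650,3.233
FDG,adult_female,True,FBP,0.846,22.07,0.7793,0.02916,0.7222,0.8365
FDG,adult_female,False,iterative,0.785,425.1,5.251,0.2412,4.779,5.724
FDG,adult_female,True,iterative,0.886,47.87,1.487,0.04684,1.395,1.579
OC,adult_male,False,FBP,0.4224,39.7,1.397,0.2584,0.8753,1.920
OC,adult_male,True,FBP,0.5055,58.34,0.4166,0.06515,0.2849,0.5483
OC,adult_male,False,iterative,0.4361,156,2.560,0.4603,1.629,3.490
OC,adult_male,True,iterative,0.5098,22.01,0.7799,0.1209,0.5356,1.024
OC,adult_female,False,FBP,0.3996,89.7,1.897,0.3588,1.173,2.622
OC,adult_female,True,FBP,0.4917,45.96,0.5404,0.08479,0.3693,0.7116
OC,adult_female,False,iterative,0.4119,246.7,3.467,0.6393,2.177,4.758
OC,adult_female,True,iterative,0.503,1.9,1.019,0.1564,0.7037,1.335
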