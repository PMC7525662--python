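target,brain,heart,lungs,liver,kidneys,intestine,urinary_bladder,remainder
brain,0.133774,2e-06,5e-06,1e-06,0.0,0.0,0.0,0.00584
heart,2e-06,0.567527,0.001327,0.000187,3.1e-05,1.2e-05,2e-06,0.00584
lungs,5e-06,0.001327,0.187284,0.000325,4.7e-05,1.5e-05,2e-06,0.00584
liver,1e-06,0.000187,0.000325,0.104047,0.000616,0.000187,1.5e-05,0.00584
kidneys,0.0,3.1e-05,4.7e-05,0.000616,0.626368,0.000616,4.7e-05,0.00584
intestine,0.0,1.2e-05,1.5e-05,0.000187,0.000616,0.187284,0.000325,0.00584
lli_wall,0.0,4e-06,5e-06,4.7e-05,0.000187,0.002104,0.001327,0.00584
urinary_bladder,0.0,2e-06,2e-06,1.5e-05,4.7e-05,0.000325,3.934539,0.00584
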