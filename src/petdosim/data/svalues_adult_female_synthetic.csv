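target,brain,heart,lungs,liver,kidneys,intestine,urinary_bladder,remainder
brain,0.15607,2e-06,5e-06,1e-06,0.0,0.0,0.0,0.006191
heart,2e-06,0.78035,0.001327,0.000187,3.1e-05,1.2e-05,2e-06,0.006191
lungs,5e-06,0.001327,0.234105,0.000325,4.7e-05,1.5e-05,2e-06,0.006191
liver,1e-06,0.000187,0.000325,0.133774,0.000616,0.000187,1.5e-05,0.006191
kidneys,0.0,3.1e-05,4.7e-05,0.000616,0.681033,0.000616,4.7e-05,0.006191
intestine,0.0,1.2e-05,1.5e-05,0.000187,0.000616,0.212823,0.000325,0.006191
lli_wall,0.0,4e-06,5e-06,4.7e-05,0.000187,0.002104,0.001327,0.006191
urinary_bladder,0.0,2e-06,2e-06,1.5e-05,4.7e-05,0.000325,5.216826,0.006191
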