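organ,w_T
brain,0.15
heart,0.12
lungs,0.18
liver,0.08
kidneys,0.09
intestine,0.18
lli_wall,0.12
urinary_bladder,0.08
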