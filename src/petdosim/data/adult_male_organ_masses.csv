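# species: adult_male
# body_mass_g: 73000
# note: editable reference fixture; reference adult male phantom organ masses
organ,mass_g
brain,1400
heart,330
lungs,1000
liver,1800
kidneys,299
intestine,1000
urinary_bladder,47.6
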