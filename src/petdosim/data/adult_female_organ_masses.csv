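# species: adult_female
# body_mass_g: 60000
# note: editable reference fixture; reference adult female phantom organ masses
organ,mass_g
brain,1200
heart,240
lungs,800
liver,1400
kidneys,275
intestine,880
urinary_bladder,35.9
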