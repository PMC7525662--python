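# species: rat
# body_mass_g: 332.67
# note: editable reference fixture with literature-typical adult rat organ masses, paired organs combined
organ,mass_g
brain,1.80
heart,1.20
lungs,1.50
liver,12.00
kidneys,2.66
intestine,10.00
urinary_bladder,0.35
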