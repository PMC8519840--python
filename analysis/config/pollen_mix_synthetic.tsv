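# SYNTHETIC stand-in for a pollen-derived amino-acid blend: unequal
# proportions (leucine/valine-rich, tryptophan-poor) over the ten essential
# amino acids, in the style of bee-collected pollen hydrolysates.  Not
# measured data; replace with assayed proportions where available.
amino_acid	proportion
arginine	0.055
histidine	0.025
isoleucine	0.125
leucine	0.180
lysine	0.150
methionine	0.040
phenylalanine	0.100
threonine	0.105
tryptophan	0.020
valine	0.200
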