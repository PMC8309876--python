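organism,concentration_spp_m3
Sagitta setosa < 10 mm,7.05
Copepoda < 1 mm,430.53
Nauplii Copepoda,38.95
Acartia clausi,0.84
Centropages kroyeri,307.37
Oithona davisae,34.74
Harpacticoida,0.63
Oikopleura dioica,0.32
Plepois polyphemoides,54.74
Noctiluca miliaris,0.11
Larvae Gastropoda,326.32
Larvae Bivalvia,0.32
Larvae Polychaeta,1.05
Larvae Decapoda,1.37
Nauplii Cirripedia,42.11
Cypris st. Ostracoda,0.11
Ova Fish,1.79
Actinotrocha,0.21
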