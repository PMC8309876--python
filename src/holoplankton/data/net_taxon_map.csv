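organism,taxon
Sagitta setosa < 10 mm,Chaetognatha
Copepoda < 1 mm,Copepoda
Nauplii Copepoda,Copepoda
Acartia clausi,Copepoda
Centropages kroyeri,Copepoda
Oithona davisae,Copepoda
Harpacticoida,Copepoda
Oikopleura dioica,Copelata
Plepois polyphemoides,Cladocera
Noctiluca miliaris,Other
Larvae Gastropoda,Other
Larvae Bivalvia,Other
Larvae Polychaeta,Other
Larvae Decapoda,Other
Nauplii Cirripedia,Other
Cypris st. Ostracoda,Other
Ova Fish,Other
Actinotrocha,Other
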