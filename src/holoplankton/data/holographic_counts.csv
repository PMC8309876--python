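taxon,concentration_spp_m3
Chaetognatha,0
Copepoda,720.33
Copelata,0
Cladocera,42.37
Other,400.84
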