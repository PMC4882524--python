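# Reconstructed full starting model for Nmass: every hypothesised pathway
# from climate (MAT, MAP) and topsoil nutrients (TSN, TSK, TSP) to the
# latent leaf-morphology factor (SLA, LS, LDW) and to foliar N.
latent LMT: SLA LS LDW
path MAT -> TSN
path MAT -> TSK
path MAT -> TSP
path MAT -> LMT
path MAT -> Nmass
path MAP -> TSN
path MAP -> TSK
path MAP -> TSP
path MAP -> LMT
path MAP -> Nmass
path TSN -> LMT
path TSN -> Nmass
path TSK -> LMT
path TSK -> Nmass
path TSP -> LMT
path TSP -> Nmass
path LMT -> Nmass
cov MAT ~~ MAP
cov TSN ~~ TSK
cov TSN ~~ TSP
cov TSK ~~ TSP
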