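# Reconstructed full starting model for Narea: every hypothesised pathway
# from climate (MAT, MAP) and topsoil nutrients (TSN, TSK, TSP) to the
# latent leaf-morphology factor (SLA, LS, LDW) and to foliar N.
latent LMT: SLA LS LDW
path MAT -> TSN
path MAT -> TSK
path MAT -> TSP
path MAT -> LMT
path MAT -> Narea
path MAP -> TSN
path MAP -> TSK
path MAP -> TSP
path MAP -> LMT
path MAP -> Narea
path TSN -> LMT
path TSN -> Narea
path TSK -> LMT
path TSK -> Narea
path TSP -> LMT
path TSP -> Narea
path LMT -> Narea
cov MAT ~~ MAP
cov TSN ~~ TSK
cov TSN ~~ TSP
cov TSK ~~ TSP
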