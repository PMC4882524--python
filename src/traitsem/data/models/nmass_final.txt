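# Final structure for mass-based leaf nitrogen (Nmass).
# Latent leaf-morphology factor measured by SLA and leaf size.
latent LMT1: SLA LS
path MAP -> TSK
path MAP -> TSP
path TSP -> LMT1
path TSK -> Nmass
path LMT1 -> Nmass
cov TSK ~~ TSP
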