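# Final structure for area-based leaf nitrogen (Narea).
# Latent leaf-morphology factor measured by SLA and leaf dry weight.
latent LMT2: SLA LDW
path MAP -> TSK
path MAP -> TSP
path TSP -> LMT2
path TSK -> Narea
path TSP -> Narea
path LMT2 -> Narea
cov TSK ~~ TSP
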