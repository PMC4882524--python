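variable,mean,se,min,max,cv
MAT,6.67,0.22,4.10,10.30,27
MAP,636.80,11.29,554.00,889.00,15
TSN,2.48,0.22,0.90,9.60,71
TSK,19.57,0.31,14.10,25.90,13
TSP,0.52,0.02,0.20,1.30,39
SLA,13.81,0.43,7.50,28.40,27
LS,35.82,1.35,19.50,72.40,28
LDW,2.70,0.20,2.70,10.20,30
Nmass,23.59,0.41,17.60,33.70,15
Narea,1.79,0.05,1.00,3.10,22
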