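,Nmass,Narea,SLA,LS,LDW,TSN,TSK,TSP,MAT,MAP
Nmass,1.000,0.064,0.630,0.390,-0.030,-0.230,0.180,-0.070,-0.170,-0.210
Narea,0.064,1.000,-0.630,-0.170,0.450,0.050,0.550,0.270,-0.040,-0.170
SLA,0.630,-0.630,1.000,0.350,-0.370,-0.190,-0.240,-0.270,-0.140,-0.010
LS,0.390,-0.170,0.350,1.000,0.690,-0.070,0.030,-0.010,-0.110,-0.030
LDW,-0.030,0.450,-0.370,0.690,1.000,0.090,0.280,0.240,-0.060,-0.020
TSN,-0.230,0.050,-0.190,-0.070,0.090,1.000,-0.080,0.030,-0.070,0.590
TSK,0.180,0.550,-0.240,0.030,0.280,-0.080,1.000,0.580,0.090,-0.530
TSP,-0.070,0.270,-0.270,-0.010,0.240,0.030,0.580,1.000,0.130,-0.360
MAT,-0.170,-0.040,-0.140,-0.110,-0.060,-0.070,0.090,0.130,1.000,-0.340
MAP,-0.210,-0.170,-0.010,-0.030,-0.020,0.590,-0.530,-0.360,-0.340,1.000
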