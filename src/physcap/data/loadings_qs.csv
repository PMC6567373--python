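measure,QS1,QS2,QS3,QS4
Range A ML,0.948,-0.107,-0.145,0.066
RMS A ML,0.933,-0.012,-0.250,0.015
SA DISPL,0.928,0.011,-0.069,0.129
SP ML DISPL,0.872,-0.142,-0.096,0.183
MV ML DISPL,0.795,-0.119,-0.105,0.203
EA DISPL,0.774,0.056,-0.115,-0.029
SP Planar DISPL,0.764,-0.056,-0.082,0.625
Range A AP,0.706,0.185,-0.107,0.432
RMS A AP,0.675,0.288,-0.144,0.296
CF AP,-0.126,-0.983,0.113,-0.003
F95 AP,-0.103,-0.918,0.141,-0.068
NJS AP,0.121,-0.789,0.106,-0.130
F50 AP,-0.129,-0.774,0.102,0.165
CF ML,-0.195,-0.201,0.957,-0.024
F95 ML,-0.263,-0.153,0.872,-0.048
NJS ML,-0.051,-0.168,0.849,-0.109
F50 ML,-0.088,-0.207,0.794,-0.010
MV AP DISPL,0.533,-0.006,-0.097,0.802
SP AP DISPL,0.626,-0.004,-0.084,0.765
SE ML,-0.169,0.030,0.230,-0.041
SE AP,0.117,-0.312,0.094,-0.073
FD ML,-0.066,0.178,-0.156,-0.112
FD AP,0.016,-0.280,0.032,-0.298
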