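measure,7MW1,7MW2,7MW3,7MW4,7MW5
Range A V,-0.916,-0.030,-0.116,0.035,-0.050
RMS A V,-0.909,-0.279,-0.106,0.046,-0.109
Range A AP,-0.882,-0.046,-0.157,0.113,-0.102
RMS A AP,-0.866,-0.183,-0.119,0.181,-0.140
Range A ML,-0.735,0.227,-0.113,0.521,-0.008
RMS A ML,-0.727,0.070,0.044,0.678,-0.012
Cadence,0.708,0.253,-0.654,0.005,0.047
Total duration,0.663,0.394,0.017,0.014,0.237
Stride Reg V,-0.163,-0.844,-0.007,-0.120,-0.158
Stride Reg AP,0.087,-0.823,-0.008,0.130,-0.174
Step Reg V,-0.279,-0.737,-0.001,-0.145,-0.223
Step Reg AP,-0.151,-0.658,-0.063,0.072,-0.215
Stride Reg ML,-0.026,-0.633,0.176,0.445,0.013
NJS V,-0.125,0.050,-0.826,-0.007,0.147
NJS AP,-0.404,-0.176,-0.662,0.078,-0.116
NJS ML,-0.179,0.064,-0.389,0.669,-0.012
Step Reg ML,-0.065,-0.387,0.204,0.557,-0.003
PCI,0.120,0.269,-0.007,0.001,0.893
SD Cadence,0.234,0.390,-0.123,-0.017,0.836
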