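measure,CST1,CST2,CST3,CST4,CST5,CST6
Sts G RMS ML,-0.904,-0.008,-0.115,-0.137,-0.003,-0.060
Sts G Range ML,-0.846,0.031,-0.160,-0.045,-0.032,-0.292
stS A RMS V,-0.836,0.118,-0.195,0.259,-0.103,0.101
stS G RMS ML,-0.832,-0.203,-0.142,-0.153,-0.245,-0.042
Sts A Range V,-0.826,0.131,-0.213,0.392,0.004,0.071
Sts A RMS V,-0.809,0.128,-0.176,0.393,0.086,0.148
stS A Range V,-0.702,0.090,-0.230,0.112,-0.395,-0.087
stS G Range ML,-0.659,-0.128,-0.173,-0.094,-0.454,-0.151
Sts JS V,-0.207,0.909,0.084,0.208,0.118,0.084
Sts JS AP,-0.054,0.909,0.071,0.238,-0.102,0.133
Sts JS ML,-0.047,0.897,-0.032,0.205,0.150,0.127
Duration Sts,0.027,0.850,0.179,0.286,0.331,0.145
SD Duration Sts,0.154,0.718,0.024,-0.109,0.026,-0.081
Total Duration,-0.039,0.706,0.173,0.529,0.277,0.243
Sts A RMS ML,-0.055,0.019,-0.938,-0.048,-0.131,-0.161
Sts A Range ML,-0.118,0.008,-0.918,0.013,-0.129,-0.245
Sts G RMS AP,-0.255,-0.086,-0.651,-0.012,-0.049,-0.100
stS A RMS ML,-0.126,-0.140,-0.644,-0.111,-0.402,-0.049
Sts G Range AP,-0.394,-0.085,-0.638,0.084,-0.037,-0.106
stS A Range ML,-0.116,-0.056,-0.511,-0.075,-0.504,-0.110
stS JS AP,-0.162,0.226,0.043,0.905,0.098,-0.122
stS JS ML,-0.106,0.291,-0.234,0.859,0.123,0.218
stS JS V,-0.348,0.304,0.059,0.836,0.143,0.173
Duration stS,-0.097,0.404,0.161,0.778,0.197,0.338
SD Duration stS,0.210,-0.080,0.151,0.595,-0.125,0.090
stS A Range AP,-0.138,-0.164,-0.292,-0.070,-0.859,-0.193
stS A RMS AP,-0.208,-0.304,-0.295,-0.136,-0.764,-0.284
Sts A Range AP,-0.084,-0.216,-0.304,-0.239,-0.229,-0.842
Sts A RMS AP,-0.138,-0.215,-0.315,-0.276,-0.224,-0.786
stS G Range AP,-0.320,-0.055,-0.402,-0.056,-0.342,0.068
stS G RMS AP,-0.221,-0.134,-0.449,-0.110,-0.317,0.105
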