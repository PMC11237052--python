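gene,weight
CCL5,0.008346
CD27,0.072293
CD274,0.042853
CD276,-0.0239
CD8A,0.031021
CMKLR1,0.151253
CXCL9,0.074135
CXCR6,0.004313
HLA-DQA1,0.020091
HLA-DRB1,0.058806
HLA-E,0.07175
IDO1,0.060679
LAG3,0.123895
NKG7,0.075524
PDCD1LG2,0.003734
PSMB10,0.003184
STAT1,0.250229
TIGIT,0.084767
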