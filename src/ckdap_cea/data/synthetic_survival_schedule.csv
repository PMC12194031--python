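year,p_death,p_transplant
1,0.12,0.045
2,0.135,0.0399
3,0.15,0.0354
4,0.165,0.0314
5,0.18,0.0278
6,0.195,0.0247
7,0.21,0.0219
8,0.225,0.0194
9,0.24,0.0172
10,0.255,0.0153
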