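case,IJF,MCVC
1,0.12,0.05
2,0.86,0.48
3,0.73,0.62
4,0.90,0.10
5,0.87,0.75
6,0.64,0.50
7,0.82,0.52
8,0.79,0.08
9,0.84,0.77
10,0.44,0.84
11,0.83,-0.06
12,0.90,0.33
13,0.37,0.20
14,0.25,0.06
15,0.82,0.54
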