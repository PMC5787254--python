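band,total,alive_12m,deceased_12m,alive_24m,deceased_24m
0.1 (0–0.15),22,22,0,19,3
0.2 (0.16–0.25),73,72,1,61,12
0.3 (0.26–0.35),61,54,7,45,16
0.4 (0.36–0.45),161,113,48,88,73
0.5 (0.46–0.55),123,50,73,36,87
0.6 (0.56–0.65),120,5,115,3,117
0.7 (0.66–1),30,0,30,0,30
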