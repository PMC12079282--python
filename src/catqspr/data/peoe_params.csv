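element,a,b,c
H,7.17,6.24,-0.56
C,7.98,9.18,1.88
N,11.54,10.82,1.36
O,14.18,12.92,1.39
F,14.66,13.85,2.31
Cl,11.0,9.69,1.35
Br,10.08,8.47,1.16
I,9.9,7.96,0.96
S,10.14,9.13,1.38
P,8.9,8.24,0.96
B,7.88,6.0,0.0
Si,7.3,6.57,0.66
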