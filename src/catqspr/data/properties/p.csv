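element,value
H,0.667
B,3.03
C,1.76
N,1.1
O,0.802
F,0.557
Si,5.38
P,3.63
S,2.9
Cl,2.18
Br,3.05
I,5.35
Ru,9.6
Rh,8.6
Os,8.5
Ir,7.6
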