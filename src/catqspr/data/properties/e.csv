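element,value
H,2.2
B,2.04
C,2.55
N,3.04
O,3.44
F,3.98
Si,1.9
P,2.19
S,2.58
Cl,3.16
Br,2.96
I,2.66
Ru,2.2
Rh,2.28
Os,2.2
Ir,2.2
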