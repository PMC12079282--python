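element,value
H,0.23
B,0.18
C,0.09
N,-0.6
O,-0.17
F,0.42
Si,0.3
P,0.86
S,0.41
Cl,0.65
Br,0.89
I,1.04
Ru,0.0
Rh,0.0
Os,0.0
Ir,0.0
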