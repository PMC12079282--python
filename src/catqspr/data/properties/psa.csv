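element,value
H,0.0
B,0.0
C,0.0
N,12.03
O,17.07
F,0.0
Si,0.0
P,13.59
S,25.3
Cl,0.0
Br,0.0
I,0.0
Ru,0.0
Rh,0.0
Os,0.0
Ir,0.0
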