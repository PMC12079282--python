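element,value
H,1.03
B,3.0
C,2.42
N,2.62
O,1.64
F,0.81
Si,7.0
P,9.0
S,7.92
Cl,5.84
Br,8.74
I,13.95
Ru,10.0
Rh,10.0
Os,11.0
Ir,11.0
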