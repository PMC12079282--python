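element,value
H,6.43
B,4.01
C,5.0
N,7.23
O,6.08
F,7.01
Si,3.38
P,4.88
S,4.14
Cl,4.68
Br,4.22
I,3.69
Ru,3.0
Rh,3.16
Os,3.8
Ir,3.8
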