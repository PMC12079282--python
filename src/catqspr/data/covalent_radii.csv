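element,value
H,0.31
B,0.84
C,0.76
N,0.71
O,0.66
F,0.57
Si,1.11
P,1.07
S,1.05
Cl,1.02
Br,1.2
I,1.39
Ru,1.46
Rh,1.42
Os,1.44
Ir,1.41
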