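element,value
H,7.238
B,29.648
C,20.58
N,15.599
O,14.71
F,13.306
Si,38.792
P,24.429
S,24.429
Cl,22.449
Br,26.522
I,32.515
Ru,36.087
Rh,33.51
Os,42.213
Ir,40.479
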