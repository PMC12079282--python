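element,value
H,0.1555209953
B,0.2493765586
C,0.2
N,0.1383125864
O,0.1644736842
F,0.1426533524
Si,0.2958579882
P,0.2049180328
S,0.2415458937
Cl,0.2136752137
Br,0.2369668246
I,0.27100271
Ru,0.3333333333
Rh,0.3164556962
Os,0.2631578947
Ir,0.2631578947
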