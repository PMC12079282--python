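element,value
H,1.008
B,10.81
C,12.011
N,14.007
O,15.999
F,18.998
Si,28.085
P,30.974
S,32.06
Cl,35.45
Br,79.904
I,126.904
Ru,101.07
Rh,102.906
Os,190.23
Ir,192.217
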