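entry,name,r0_M_per_s,kcat,kcat_units,split,P_atm,T_C,M_mM,Q_mM,solvent,ref
1,[Rh(COD)(PPh3)2]+,2.35e-7,51.2,M-2 s-1,train,1,100,0.3,85,toluene,ref53
2,[Rh(COD)(NCPh)(PPh3)]+,2.78e-6,,,train,5,50,20,600,CH2Cl2,ref63
3,[Rh(COD)(NCPh)2]+,2.88e-5,,,train,5,50,20,600,CH2Cl2,ref63
4,[Ir(COD)(NCPh)(PPh3)]+,6.11e-6,,,train,5,50,20,600,CH2Cl2,ref63
5,[Ir(COD)(NCPh)2]+,1.83e-5,,,train,5,50,20,600,CH2Cl2,ref63
6,RuHCl(CO)(piperidine)(PPh3)2,7.80e-7,2.0,M-2 s-1,train,4,130,1.2,120,xylene,unpublished
7,RuHCl(PPh3)3,1.32e-6,,,train,5,130,1.0,105,xylene,ref59-ref61
8,RhCl(PPh3)3,6.58e-7,,,train,20,85,5.0,50,benzene,ref61
9,[Cp*Rh(NCMe)3]2+,3.56e-6,,,train,30,40,3.3,66.7,CH2Cl2,ref62
10,[Rh(dppe)2]+,6.12e-6,13.5,M-2 s-1,train,4,130,1.0,96,xylene,ref57
11,[Rh(Q)2(k2-triphos)]+,1.05e-5,22.04,M-2 s-1,train,4,130,1.0,96,xylene,ref56
12,[Ir(Q)2(k2-triphos)]+,7.24e-7,3.26,M-1 s-1,train,4,130,1.0,96,xylene,ref56
13,[RuH(CO)(NCMe)2(PPh3)2]+,6.74e-7,28.5,M-2 s-1,train,1,125,0.8,85,xylene,ref54
14,[OsH(CO)(NCMe)2(PPh3)2]+,1.32e-6,47.0,M-2 s-1,train,1,125,1.0,85,xylene,ref64
15,RuH(CO)(k3-OCOCH2Cl)(PPh3)2,6.13e-7,,,train,4,130,1.0,170,xylene,ref65
16,RuH(CO)(k3-OCOC6H5)(PPh3)2,6.94e-7,,,train,4,130,1.0,170,xylene,ref65
17,RuH(CO)(k3-OCOCH3)(PPh3)2,9.24e-7,,,train,4,130,1.0,170,xylene,ref65
18,RuH(CO)(k3-OCOCH(CH3)2)(PPh3)2,8.00e-7,,,train,4,130,1.0,170,xylene,ref65
19,OsH(CO)(k3-OCOCH2Cl)(PPh3)2,2.05e-7,,,train,4,130,1.0,170,xylene,ref65
20,OsH(CO)(k3-OCOC6H5)(PPh3)2,3.51e-7,,,train,4,130,1.0,170,xylene,ref65
21,OsH(CO)(k3-OCOCH3)(PPh3)2,4.23e-7,,,train,4,130,1.0,170,xylene,ref65
22,OsH(CO)(k3-OCOCH(CH3)2)(PPh3)2,2.65e-7,,,train,4,130,1.0,170,xylene,ref65
23,OsHCl(CO)(PPh3)3,7.85e-7,0.04,M-1 s-1,train,4,130,1.0,100,xylene,ref66
24,Rh(acac)(CO)(PtBu(CH2CH=CH2)2),1.41e-5,6.31,M-1 s-1,train,4,130,6.5,80,xylene,ref58
25,[Ru(NCMe)3(triphos)]2+,1.30e-6,6.9e-4,M-1 s-1,train,4,130,1.0,96,xylene,unpublished
37,IrH(CO)(PPh3)3,7.20e-7,,,test,4,150,1.0,96,xylene,unpublished
55,Rh(acac)(CO)2,1.58e-5,,,test,4,130,1.0,100,xylene,unpublished
59,Rh(acac)(CO)(PPh3),1.75e-5,,,test,4,130,1.0,100,xylene,unpublished
177,Rh(acac)(CO)(PtBu(CH2CN)2),1.32e-6,,,test,4,130,1.0,100,xylene,unpublished
178,RhH(CO)(PPh3)3,1.09e-5,,,test,4,130,1.0,100,xylene,unpublished
179,Rh(COE)2(Q)2+,2.00e-7,,,test,4,130,1.0,100,xylene,unpublished
180,Ir(COE)2(Q)2+,5.98e-7,,,test,4,130,1.0,100,xylene,unpublished
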