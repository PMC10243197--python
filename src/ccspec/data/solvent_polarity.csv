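solvent,polarity
Water,1.000
Methanol,0.762
Ethanol,0.654
1-Propanol,0.617
2-Propanol,0.546
1-Butanol,0.586
Acetonitrile,0.460
DMSO,0.444
DMF,0.386
Acetone,0.355
Dichloromethane,0.309
Chloroform,0.259
Ethyl acetate,0.228
THF,0.207
Diethyl ether,0.117
Toluene,0.099
Hexane,0.009
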