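chemical,matrix,min,max,mean,sd,n_refs,printed_min,printed_max,printed_mean,printed_sd
formaldehyde,e-liquid,0,0.197,0.00541,0.0208,7,0,0.197,0.00541,0.0208
acetaldehyde,e-liquid,0,0.0429,0.00303,0.00568,2,0,0.0429,0.00303,0.00568
acetone,e-liquid,0,0.001,0.0000861,0.000216,2,0,0.001,0.0000861,0.000216
acrolein,e-liquid,0,0.327,0.0306,0.0704,2,0,0.327,0.0306,0.0704
As,e-liquid,0,0.00043,0.0000272,0.0000927,4,0,0.00043,0.0000272,0.0000927
Cd,e-liquid,0.00000001,0.00022,0.0000758,0.0000593,6,0.00000001,0.00022,0.0000758,0.0000593
Mn,e-liquid,0,0.00691,0.000635,0.00179,4,0,0.00691,0.000635,0.00179
Pb,e-liquid,0,0.0135,0.000525,0.00188,7,0,0.0135,0.000525,0.00188
Cu,e-liquid,0,0.927,0.105,0.241,5,0,0.927,0.105,0.241
Ni,e-liquid,0,0.0613,0.00393,0.011,6,0,0.0613,0.00393,0.011
Cr,e-liquid,0,0.00211,0.000134,0.000329,8,0,0.00211,0.000134,0.000329
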