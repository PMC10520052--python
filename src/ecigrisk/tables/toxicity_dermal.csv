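chemical,rel_ug_m3,rfc_ug_m3,cpv_inh,rfd_oral,cpv_oral,rfd_derm,sf_derm,ld50_oral,ld50_derm,source
formaldehyde,,,,,,,,,2700,animal LD50 compilation
acetone,,,,,,,,,20000,animal LD50 compilation
acrolein,,,,,,,,,562,animal LD50 compilation
As,,,,,,0.000123,3.66,,145,USEPA RfD; dermal SF; animal LD50
Cd,,,,,,0.00001,6.10,,,USEPA RfD; dermal SF
Mn,,,,,,0.00184,,,,USEPA RfD
Cu,,,,,,0.012,,,,USEPA RfD
Pb,,,,,,0.000525,0.017,,,USEPA RfD; dermal SF
Ni,,,,,,0.0054,,,,USEPA RfD
Cr,,,,,,0.00006,20,,,USEPA RfD; dermal SF
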