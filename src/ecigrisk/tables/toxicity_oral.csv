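chemical,rel_ug_m3,rfc_ug_m3,cpv_inh,rfd_oral,cpv_oral,rfd_derm,sf_derm,ld50_oral,ld50_derm,source
formaldehyde,,,,0.2,,,,800,,USEPA RfD; animal LD50
acetaldehyde,,,,,,,,1930,,animal LD50 compilation
acetone,,,,0.9,,,,5800,,USEPA RfD; animal LD50
acrolein,,,,0.0005,,,,46,,USEPA RfD; animal LD50
As,,,,0.0003,1.50,,,763,,USEPA RfD/CPV; animal LD50
Cd,,,,0.0005,0.5,,,,,USEPA RfD; oral CPV
Mn,,,,0.14,,,,,,USEPA RfD
Cu,,,,0.04,,,,,,USEPA RfD
Pb,,,,0.0035,0.0085,,,,,USEPA RfD; oral CPV
Ni,,,,0.02,,,,,,USEPA RfD
Cr,,,,0.003,0.42,,,,,USEPA RfD; oral CPV
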