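chemical,rel_ug_m3,rfc_ug_m3,cpv_inh,rfd_oral,cpv_oral,rfd_derm,sf_derm,ld50_oral,ld50_derm,source
formaldehyde,9,,0.021,,,,,,,OEHHA REL; OEHHA CPV
acetaldehyde,140,9,0.01,,,,,,,OEHHA REL/CPV; USEPA RfC
acrolein,0.35,0.02,,,,,,,,OEHHA REL; USEPA RfC
As,0.015,,12,,,,,,,OEHHA
Cd,0.02,,15,,,,,,,OEHHA
Mn,0.09,0.05,,,,,,,,OEHHA REL; USEPA RfC
Cu,,0.0402,,,,,,,,USEPA
Pb,0.5,,0.042,,,,,,,OEHHA
Ni,0.014,,0.91,,,,,,,OEHHA
Cr,0.2,0.0083,510,,,,,,,OEHHA REL/CPV; USEPA RfC
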