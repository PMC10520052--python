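chemical,printed,resolved_rel_ug_m3,resolved_cpv_inh,resolved_rfc_ug_m3,basis
acetaldehyde,1400.0019,140,0.01,9,CPV 0.01 (OEHHA) is the only potency that reproduces the published mean inhalation cancer risk 1.57e-5; REL 140 and RfC 9 reproduce the published HQ 0.61
Cd,0.0215-,0.02,15,,REL 0.02 reproduces the published Cd inhalation HQ 2.29e-3; CPV 15 reproduces the published cancer risk 1.97e-7
Cr,0.25100.0083,0.2,510,0.0083,CPV 510 times the published Cr inhalation dose 8.62e-7 reproduces the published cancer risk 4.39e-4
As,0.01512-,0.015,12,,REL 0.015 reproduces the published As inhalation HQ 1.31e-1; CPV 12 reproduces the cancer risk 6.74e-6
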