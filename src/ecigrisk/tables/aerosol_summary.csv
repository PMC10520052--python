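chemical,matrix,min,max,mean,sd,n_refs,printed_min,printed_max,printed_mean,printed_sd
formaldehyde,aerosol,0,28.1,0.864,3.32,12,0,28.1,0.864,3.32
acetaldehyde,aerosol,0,22.5,0.673,2.78,12,0,22.5,0.673,2.78
acetone,aerosol,0,1.66,0.242,0.396,7,0,4.11,0.373,0.753
acrolein,aerosol,0,4.11,0.373,0.753,5,0,1.66,0.242,0.396
As,aerosol,0,0.00174,0.000241,0.000379,3,0,0.00174,0.000241,0.000379
Cd,aerosol,0,0.0001,0.00000563,0.000017,6,0,0.0001,0.00000563,0.000017
Mn,aerosol,0.00005,0.0321,0.00675,0.0108,4,0.00005,0.0321,0.00675,0.0108
Pb,aerosol,0,0.236,0.00376,0.0237,8,0,0.236,0.00376,0.0237
Cu,aerosol,0.00002,0.384,0.0347,0.0805,6,0.00002,0.384,0.0347,0.0805
Ni,aerosol,0.0000000015,0.738,0.0147,0.0899,9,0.0000000015,0.738,0.0147,0.0899
Cr,aerosol,0,0.0158,0.00037,0.00148,9,0,0.0158,0.00037,0.00148
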