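patient,predictor,T1-T2,T2-T3,T3-T4,sign_kept
P1,PWS,P,P,,True
P2,PWS,P,P,NS,False
P3,PWS,P,P,P,True
P4,PWS,P,NS,,False
P5,PWS,P,P,,True
P6,PWS,P,P,NS,False
P7,PWS,NS,NS,,False
P8,PWS,NS,P,,False
P9,PWS,P,NS,,False
P10,PWS,P,,,False
P11,PWS,P,NS,,False
P12,PWS,P,NS,NS,False
P13,PWS,P,NS,P,False
P14,PWS,NS,NS,N,False
P15,PWS,NS,P,,False
P16,PWS,NS,P,P,False
P1,FSS,P,N,,False
P2,FSS,N,NS,NS,False
P3,FSS,NS,NS,N,False
P4,FSS,NS,N,,False
P5,FSS,N,NS,,False
P6,FSS,NS,NS,NS,False
P7,FSS,N,N,,True
P8,FSS,N,NS,,False
P9,FSS,N,N,,True
P10,FSS,N,,,False
P11,FSS,NS,N,,False
P12,FSS,N,NS,NS,False
P13,FSS,NS,N,NS,False
P14,FSS,NS,NS,NS,False
P15,FSS,NS,NS,,False
P16,FSS,NS,N,N,False
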