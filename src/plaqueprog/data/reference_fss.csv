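patient,period,nodes,p,r
P1,T1-T2,800,0.0000,0.7795
P1,T2-T3,800,0.0048,-0.1168
P2,T1-T2,800,0.0003,-0.1432
P2,T2-T3,900,0.7463,0.0132
P2,T3-T4,900,0.5646,-0.0157
P3,T1-T2,700,0.0787,-0.0495
P3,T2-T3,800,0.2754,-0.0303
P3,T3-T4,800,0.0000,-0.1859
P4,T1-T2,700,0.8717,0.0074
P4,T2-T3,700,0.0316,-0.0761
P5,T1-T2,900,0.0026,-0.1257
P5,T2-T3,900,0.0535,-0.0538
P6,T1-T2,800,0.3243,0.0256
P6,T2-T3,800,0.5825,-0.0165
P6,T3-T4,800,0.0757,-0.0459
P7,T1-T2,700,0.0015,-0.1208
P7,T2-T3,400,0.0002,-0.1705
P8,T1-T2,400,0.0051,-0.1524
P8,T2-T3,900,0.0909,0.0553
P9,T1-T2,700,0.0000,-0.2104
P9,T2-T3,700,0.0012,-0.1732
P10,T1-T2,400,0.0003,-0.0749
P11,T1-T2,800,0.4927,0.0207
P11,T2-T3,900,0.0003,-0.1034
P12,T1-T2,800,0.0000,-0.0900
P12,T2-T3,800,0.2037,-0.0482
P12,T3-T4,800,0.1904,0.0376
P13,T1-T2,600,0.1071,-0.0864
P13,T2-T3,600,0.0281,-0.0865
P13,T3-T4,500,0.6058,0.0355
P14,T1-T2,700,0.6729,0.0127
P14,T2-T3,700,0.4306,-0.0322
P14,T3-T4,600,0.0788,-0.0591
P15,T1-T2,1000,0.8519,-0.0044
P15,T2-T3,1000,0.4461,0.0220
P16,T1-T2,900,0.5383,0.0179
P16,T2-T3,800,0.0071,-0.0906
P16,T3-T4,800,0.0082,-0.0853
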