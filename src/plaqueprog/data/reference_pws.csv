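patient,period,nodes,p,r
P1,T1-T2,800,0.0000,0.6048
P1,T2-T3,800,0.0019,0.0972
P2,T1-T2,800,0.0000,0.2946
P2,T2-T3,900,0.0000,0.0889
P2,T3-T4,900,0.1063,-0.0508
P3,T1-T2,700,0.0000,0.1222
P3,T2-T3,800,0.0014,0.0573
P3,T3-T4,800,0.0042,0.0904
P4,T1-T2,700,0.0000,0.1512
P4,T2-T3,700,0.6773,-0.0108
P5,T1-T2,900,0.0000,0.1889
P5,T2-T3,900,0.0066,0.0600
P6,T1-T2,800,0.0020,0.0449
P6,T2-T3,800,0.0000,0.1304
P6,T3-T4,800,0.1876,-0.0249
P7,T1-T2,700,0.1892,0.0160
P7,T2-T3,400,0.3004,0.0266
P8,T1-T2,400,0.8234,0.0049
P8,T2-T3,900,0.0038,0.0536
P9,T1-T2,700,0.0053,0.0422
P9,T2-T3,700,0.3353,-0.0258
P10,T1-T2,400,0.0279,0.0244
P11,T1-T2,800,0.0080,0.0519
P11,T2-T3,900,0.1847,-0.0228
P12,T1-T2,800,0.0000,0.1727
P12,T2-T3,800,0.0633,0.0323
P12,T3-T4,800,0.0655,0.0477
P13,T1-T2,600,0.0000,0.2123
P13,T2-T3,600,0.8811,0.0051
P13,T3-T4,500,0.0000,0.3827
P14,T1-T2,700,0.2534,-0.0199
P14,T2-T3,700,0.1829,0.0393
P14,T3-T4,600,0.0149,-0.0793
P15,T1-T2,1000,0.3021,-0.0162
P15,T2-T3,1000,0.0006,0.0644
P16,T1-T2,900,0.1409,-0.0446
P16,T2-T3,800,0.0000,0.1858
P16,T3-T4,800,0.0001,0.1129
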