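group,phenotypes,chrom,size_mb
QG1,DBN;DBL,X,0.70
QG2,DST,2L,1.91
QG3,DBN,2L,0.60
QG4,LBN,2L,2.03
QG5,LWA;LBN,2L,1.17
QG6,LST,2L,0.75
QG7,DST;DBN;LBL;DBL,2c,7.92
QG8,DBL,3L,0.90
QG9,LBL,3L,0.27
QG10,LST;DST;LBN;DBL,3L,0.64
QG11,LWA;DWA;LBN,3R,1.21
QG12,DWA,3R,0.85
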