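model,trait,predictor,unit,nrmse,cor
GBLUP,Yield,G,B2IR,0.2244,0.1151
GBLUP,Yield,E+G,B2IR,0.5800,0.1960
GBLUP,Yield,G,B5IR,0.3678,0.2025
GBLUP,Yield,E+G,B5IR,0.3757,0.2242
GBLUP,Yield,G,BDRT,0.3343,0.1682
GBLUP,Yield,E+G,BDRT,0.1183,0.2004
GBLUP,Yield,G,BLHT,0.1087,0.1979
GBLUP,Yield,E+G,BLHT,0.1370,0.3071
GBLUP,Maturity,G,B2IR,0.0650,0.4312
GBLUP,Maturity,E+G,B2IR,0.1242,0.6294
GBLUP,Maturity,G,B5IR,0.1140,0.5775
GBLUP,Maturity,E+G,B5IR,0.1092,0.5846
GBLUP,Maturity,G,BDRT,0.0789,0.3197
GBLUP,Maturity,E+G,BDRT,0.0307,0.5376
GBLUP,Height,G,B2IR,0.0482,0.2779
GBLUP,Height,E+G,B2IR,0.0888,0.3433
GBLUP,Height,G,B5IR,0.1178,0.2243
GBLUP,Height,E+G,B5IR,0.0873,0.2493
GBLUP,Height,G,BDRT,0.1392,0.1805
GBLUP,Height,E+G,BDRT,0.1047,0.2097
GBLUP,Heading,G,B2IR,0.0708,0.5594
GBLUP,Heading,E+G,B2IR,0.1232,0.7642
GBLUP,Heading,G,B5IR,0.1197,0.7412
GBLUP,Heading,E+G,B5IR,0.1097,0.7558
GBLUP,Heading,G,BDRT,0.0970,0.4528
GBLUP,Heading,E+G,BDRT,0.0512,0.6449
GBLUP,Germination,G,B2IR,0.1004,0.0907
GBLUP,Germination,E+G,B2IR,0.0723,0.0895
GBLUP,Germination,G,B5IR,0.0735,0.0308
GBLUP,Germination,E+G,B5IR,0.0651,0.0314
GBLUP,Germination,G,BDRT,0.1727,0.0685
GBLUP,Germination,E+G,BDRT,0.1823,0.0680
DL,Yield,G,B2IR,0.2344,0.0688
DL,Yield,E+G,B2IR,0.2226,0.2072
DL,Yield,G,B5IR,0.3679,0.1323
DL,Yield,E+G,B5IR,0.3679,0.2183
DL,Yield,G,BDRT,0.3345,0.0444
DL,Yield,E+G,BDRT,0.3366,0.1612
DL,Yield,G,BLHT,0.1080,-0.0262
DL,Yield,E+G,BLHT,0.1094,0.2590
DL,Maturity,G,B2IR,0.0660,0.1832
DL,Maturity,E+G,B2IR,0.0614,0.6697
DL,Maturity,G,B5IR,0.1133,0.6127
DL,Maturity,E+G,B5IR,0.1146,0.6216
DL,Maturity,G,BDRT,0.0801,0.2058
DL,Maturity,E+G,BDRT,0.0760,0.6061
DL,Height,G,B2IR,0.0502,0.0721
DL,Height,E+G,B2IR,0.0482,0.2900
DL,Height,G,B5IR,0.1171,0.1943
DL,Height,E+G,B5IR,0.1189,0.2629
DL,Height,G,BDRT,0.1392,0.0875
DL,Height,E+G,BDRT,0.1403,0.1894
DL,Heading,G,B2IR,0.0754,0.5039
DL,Heading,E+G,B2IR,0.0568,0.8158
DL,Heading,G,B5IR,0.1210,0.7732
DL,Heading,E+G,B5IR,0.1202,0.7894
DL,Heading,G,BDRT,0.1051,0.4359
DL,Heading,E+G,BDRT,0.0953,0.6551
DL,Germination,G,B2IR,0.1012,0.0447
DL,Germination,E+G,B2IR,0.1002,0.0352
DL,Germination,G,B5IR,0.0726,0.0184
DL,Germination,E+G,B5IR,0.0730,0.0134
DL,Germination,G,BDRT,0.1728,0.0357
DL,Germination,E+G,BDRT,0.1690,0.1063
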