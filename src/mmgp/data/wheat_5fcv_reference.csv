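model,trait,predictor,nrmse,nrmse_sd,cor,cor_sd
GBLUP,Yield,E+G,0.0932,0.0008,0.9203,0.0024
GBLUP,Yield,E+G+GE,0.0908,0.0010,0.9245,0.0023
GBLUP,Maturity,E+G,0.0259,0.0002,0.9181,0.0010
GBLUP,Maturity,E+G+GE,0.0256,0.0002,0.9199,0.0008
GBLUP,Height,E+G,0.0536,0.0006,0.7674,0.0091
GBLUP,Height,E+G+GE,0.0532,0.0006,0.7711,0.0093
GBLUP,Heading,E+G,0.0405,0.0006,0.8683,0.0060
GBLUP,Heading,E+G+GE,0.0399,0.0006,0.8725,0.0058
GBLUP,Germination,E+G,0.0820,0.0024,0.5721,0.0141
GBLUP,Germination,E+G+GE,0.0820,0.0025,0.5727,0.0142
DL,Yield,E+G,0.0940,0.0011,0.9189,0.0032
DL,Yield,E+G+GE,0.0923,0.0014,0.9220,0.0029
DL,Maturity,E+G,0.0249,0.0002,0.9249,0.0011
DL,Maturity,E+G+GE,0.0252,0.0003,0.9229,0.0012
DL,Height,E+G,0.0545,0.0013,0.7588,0.0163
DL,Height,E+G+GE,0.0541,0.0006,0.7628,0.0088
DL,Heading,E+G,0.0376,0.0011,0.8885,0.0080
DL,Heading,E+G+GE,0.0389,0.0008,0.8798,0.0062
DL,Germination,E+G,0.0823,0.0025,0.5689,0.0166
DL,Germination,E+G+GE,0.0825,0.0024,0.5685,0.0160
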