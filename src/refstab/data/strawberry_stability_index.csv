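scope,gene,n,mean_cq,sd,cv_pct,slope,intercept,stability_index
RCF,FaRIB413,20,8.341,0.239,2.860,0.004,8.329,0.011
RCF,FaCHC1,20,23.085,0.201,0.869,0.021,23.024,0.018
RCF,FaTUBb,20,22.334,0.359,1.609,0.015,22.289,0.024
RCF,FaACTIN,20,23.894,0.309,1.294,0.144,24.326,0.186
RCF,FaTIM1,20,22.602,0.359,1.587,0.151,23.054,0.239
RCF,FaMT1,20,25.622,0.449,1.753,0.143,25.193,0.251
RCF,FaEF1a,20,17.406,0.413,2.371,0.161,17.889,0.382
RCF,FaFHA1,20,23.258,0.643,2.765,0.204,23.870,0.564
RCF,FaTUBa,20,22.899,1.174,5.128,0.556,24.567,2.851
RCF,FaBZIP1,20,30.089,1.485,4.936,0.607,28.270,2.994
RCF,FaUBQ1,20,26.677,1.249,4.680,0.812,29.113,3.800
RCF,FaGAPDH2,20,17.073,1.071,6.274,0.622,18.939,3.903
RCF,FaGAPDH1,20,24.080,1.715,7.120,1.115,27.425,7.939
FCF,FaGAPDH1,20,23.530,0.316,1.345,0.005,23.545,0.007
FCF,FaTUBa,20,21.462,0.322,1.499,0.019,21.518,0.028
FCF,FaUBQ1,20,25.599,0.405,1.583,0.047,25.458,0.074
FCF,FaGAPDH2,20,16.274,0.331,2.031,0.062,16.090,0.125
FCF,FaACTIN,20,23.539,0.314,1.335,0.136,23.133,0.181
FCF,FaEF1a,20,16.556,0.250,1.510,0.130,16.166,0.196
FCF,FaTIM1,20,24.031,0.372,1.549,0.131,23.638,0.203
FCF,FaCHC1,20,23.929,0.467,1.953,0.121,23.568,0.235
FCF,FaTUBb,20,21.668,0.387,1.784,0.133,21.271,0.236
FCF,FaBZIP1,20,27.780,0.478,1.719,0.164,27.288,0.282
FCF,FaFHA1,20,23.606,0.545,2.308,0.213,22.969,0.490
FCF,FaRIB413,20,8.635,0.323,3.736,0.158,8.161,0.590
FCF,FaMT1,20,25.910,0.745,2.876,0.425,24.635,1.222
FCC,FaUBQ1,32,27.734,0.486,1.752,0.037,27.567,0.065
FCC,FaRIB413,32,7.873,0.241,3.057,0.027,7.752,0.083
FCC,FaGAPDH1,32,25.569,0.453,1.771,0.064,25.282,0.113
FCC,FaCHC1,32,24.988,0.492,1.968,0.067,24.687,0.131
FCC,FaEF1a,32,17.786,0.386,2.173,0.062,17.509,0.134
FCC,FaGAPDH2,32,19.286,0.352,1.825,0.090,18.880,0.165
FCC,FaMT1,32,22.968,0.571,2.486,0.068,22.664,0.168
FCC,FaFHA1,32,23.875,0.651,2.728,0.062,24.156,0.170
FCC,FaTIM1,32,25.885,0.813,3.139,0.116,25.363,0.364
FCC,FaTUBb,32,22.086,0.622,2.818,0.136,21.472,0.384
FCC,FaTUBa,32,20.298,0.585,2.883,0.136,19.687,0.392
FCC,FaACTIN,32,24.440,0.563,2.303,0.211,23.493,0.485
FCC,FaBZIP1,32,25.229,0.929,3.682,0.279,23.975,1.026
FCP,FaTUBa,32,20.767,0.423,2.036,0.007,20.737,0.014
FCP,FaACTIN,32,23.676,0.364,1.536,0.013,23.528,0.020
FCP,FaRIB413,32,8.816,0.237,2.685,0.027,8.695,0.072
FCP,FaBZIP1,32,24.874,0.620,2.493,0.034,25.025,0.084
FCP,FaEF1a,32,17.574,0.437,2.485,0.034,17.727,0.084
FCP,FaGAPDH2,32,18.321,0.357,1.946,0.064,18.611,0.125
FCP,FaMT1,32,22.583,0.517,2.288,0.065,22.293,0.148
FCP,FaTUBb,32,22.009,0.574,2.609,0.100,21.561,0.260
FCP,FaCHC1,32,24.874,0.735,2.954,0.139,25.499,0.411
FCP,FaUBQ1,32,27.470,0.766,2.788,0.169,28.246,0.472
FCP,FaTIM1,32,25.223,0.755,2.993,0.193,26.091,0.577
FCP,FaFHA1,32,24.264,0.774,3.191,0.224,25.270,0.713
FCP,FaGAPDH1,32,25.419,1.120,4.405,0.263,26.600,1.156
FAP,FaGAPDH1,28,26.129,0.632,2.418,0.004,26.143,0.009
FAP,FaGAPDH2,28,18.484,0.374,2.024,0.025,18.585,0.051
FAP,FaACTIN,28,23.640,0.428,1.812,0.030,23.760,0.054
FAP,FaEF1a,28,18.780,0.417,2.219,0.026,18.886,0.059
FAP,FaMT1,28,23.992,0.506,2.108,0.028,23.879,0.060
FAP,FaFHA1,28,24.251,0.570,2.349,0.036,24.107,0.085
FAP,FaTUBb,28,21.575,0.374,1.734,0.090,21.216,0.155
FAP,FaCHC1,28,26.339,0.404,1.536,0.120,26.816,0.184
FAP,FaBZIP1,28,26.410,0.446,1.688,0.110,25.971,0.185
FAP,FaTIM1,28,26.864,0.481,1.790,0.116,26.401,0.207
FAP,FaUBQ1,28,27.650,0.642,2.322,0.115,27.085,0.266
FAP,FaRIB413,28,8.790,0.444,5.053,0.061,9.036,0.310
FAP,FaTUBa,28,20.281,0.595,2.931,0.211,19.436,0.620
HCY,FaGAPDH1,36,25.817,0.479,1.856,0.024,25.938,0.045
HCY,FaUBQ1,36,28.954,0.518,1.789,0.026,29.085,0.047
HCY,FaGAPDH2,36,19.183,0.278,1.451,0.038,18.993,0.055
HCY,FaRIB413,36,8.838,0.523,5.912,0.016,8.760,0.093
HCY,FaCHC1,36,26.297,0.482,1.832,0.080,25.895,0.147
HCY,FaTUBa,36,23.058,0.586,2.542,0.093,22.591,0.237
HCY,FaFHA1,36,25.649,0.615,2.396,0.101,25.145,0.242
HCY,FaEF1a,36,18.593,0.442,2.375,0.119,17.996,0.284
HCY,FaMT1,36,25.669,0.726,2.829,0.165,24.846,0.466
HCY,FaTIM1,36,27.336,0.800,2.928,0.176,26.457,0.514
HCY,FaTUBb,36,23.573,0.775,3.286,0.218,22.484,0.716
HCY,FaBZIP1,36,27.459,0.845,3.079,0.262,26.150,0.806
HCY,FaACTIN,36,25.122,0.979,3.899,0.325,23.499,1.265
HCC,FaTIM1,24,25.850,0.974,3.766,0.003,25.862,0.013
HCC,FaGAPDH2,24,17.889,0.300,1.679,0.013,17.843,0.022
HCC,FaRIB413,24,8.426,0.299,3.551,0.021,8.498,0.073
HCC,FaUBQ1,24,27.222,0.566,2.079,0.039,27.322,0.081
HCC,FaCHC1,24,24.163,0.427,1.767,0.129,23.712,0.228
HCC,FaBZIP1,24,25.344,0.523,2.063,0.163,25.914,0.336
HCC,FaEF1a,24,16.478,0.413,2.505,0.151,15.950,0.377
HCC,FaTUBa,24,20.364,0.539,2.649,0.236,19.538,0.625
HCC,FaMT1,24,24.533,0.550,2.240,0.282,23.545,0.632
HCC,FaFHA1,24,23.116,0.612,2.646,0.246,22.256,0.650
HCC,FaACTIN,24,23.145,0.776,3.352,0.343,21.943,1.151
HCC,FaGAPDH1,24,20.908,0.836,3.999,0.401,22.313,1.605
HCC,FaTUBb,24,20.592,0.964,4.681,0.436,19.067,2.040
ALL,FaACTIN,192,24.011,0.883,3.676,0.004,23.905,0.015
ALL,FaRIB413,192,8.542,0.490,5.736,0.056,8.306,0.323
ALL,FaTUBb,192,22.073,1.067,4.835,0.069,22.252,0.333
ALL,FaEF1a,192,17.716,0.904,5.100,0.082,17.270,0.416
ALL,FaMT1,192,24.338,1.399,5.747,0.097,24.857,0.560
ALL,FaFHA1,192,24.140,1.037,4.298,0.144,23.426,0.619
ALL,FaTUBa,192,21.292,1.305,6.131,0.158,21.937,0.970
ALL,FaGAPDH1,192,24.722,1.856,7.509,0.157,25.119,1.175
ALL,FaUBQ1,192,27.492,1.134,4.124,0.295,26.149,1.217
ALL,FaGAPDH2,192,18.270,1.063,5.818,0.267,17.007,1.551
ALL,FaCHC1,192,25.000,1.189,4.756,0.333,23.479,1.583
ALL,FaBZIP1,192,26.547,1.789,6.741,0.489,28.697,3.297
ALL,FaTIM1,192,25.650,1.591,6.201,0.619,22.923,3.839
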