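province,2008,2009,2010,2011,2012,2013,2014,2015,2016
Beijing,1.053,0.243,0.384,0.377,0.368,0.366,0.295,0.164,0.252
Tianjin,0.253,0.196,0.262,0.350,1.013,1.009,1.000,0.576,0.235
Hebei,0.448,0.384,0.413,0.368,0.328,0.344,0.313,0.304,1.057
Shanxi,0.409,0.309,0.322,0.284,0.287,0.286,0.260,0.218,0.461
Inner Mongolia,0.331,0.294,0.247,0.258,0.236,0.244,0.225,0.228,0.453
Liaoning,0.483,0.390,0.372,0.342,0.329,0.413,0.421,0.336,0.492
Jilin,1.034,0.187,0.203,0.277,0.265,0.231,0.260,0.241,0.193
Heilongjiang,0.387,0.234,0.280,0.274,0.213,0.235,0.273,0.305,0.241
Shanghai,1.889,1.510,1.412,1.376,1.278,1.268,1.000,1.339,1.060
Jiangsu,1.091,1.093,1.170,1.118,1.102,1.106,1.000,1.118,1.083
Zhejiang,1.129,1.002,0.483,0.503,0.495,0.407,0.413,0.391,0.179
Anhui,0.536,0.495,0.369,0.333,0.339,0.401,0.414,0.381,1.063
Fujian,1.421,1.158,1.063,0.750,0.622,0.588,0.575,0.466,0.525
Jiangxi,0.458,0.456,0.341,0.354,0.318,0.410,0.388,0.415,0.574
Shandong,0.435,0.461,0.386,0.534,0.433,0.422,0.397,0.383,1.011
Henan,0.466,0.457,0.469,0.454,0.424,0.450,0.480,0.471,0.808
Hubei,0.551,0.727,0.776,1.067,1.057,1.043,1.000,1.023,1.156
Hunan,0.477,0.532,0.507,0.619,0.513,0.726,0.810,1.004,0.792
Guangdong,1.196,1.334,1.425,1.334,1.278,1.285,1.000,1.095,1.232
Guangxi,0.322,1.077,0.655,0.572,0.560,0.609,0.716,0.584,0.568
Hainan,2.683,1.355,1.451,1.478,1.352,1.501,1.000,1.231,1.075
Chongqing,1.155,1.042,1.100,1.104,1.159,1.168,1.000,1.161,1.194
Sichuan,1.211,1.129,1.114,1.043,1.022,0.842,0.696,0.648,0.716
Guizhou,0.788,1.038,1.037,1.039,0.640,0.671,0.550,0.540,0.736
Yunnan,0.704,1.025,0.719,0.616,0.599,0.560,0.547,0.646,0.687
Shaanxi,0.338,0.394,0.327,0.350,0.386,0.381,0.376,0.324,0.467
Gansu,0.531,0.468,0.382,0.398,0.315,0.348,0.379,0.361,0.573
Qinghai,1.190,1.134,0.625,0.647,0.542,1.000,1.000,1.029,0.602
Ningxia,1.363,1.726,1.000,1.000,1.911,1.000,1.000,1.000,2.147
Xinjiang,0.673,0.574,0.502,0.429,0.424,0.379,0.402,0.351,0.533
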