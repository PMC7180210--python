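id,gamma,beta,B,V_pat,lambda_1,lambda_2,lambda_3,lambda_4,lambda_5
01,0.769,1.650,865.45,5530.04,0.405,0.418,0.512,0.513,0.521
02,0.388,0.867,885.42,4666.08,0.385,0.498,0.558,0.706,0.709
03,0.510,1.617,863.97,5265.93,0.326,0.393,0.413,0.480,0.549
04,0.323,0.424,854.15,5984.70,0.522,0.544,0.604,0.878,0.888
05,0.061,1.381,971.67,7734.16,0.192,0.321,0.334,0.367,0.419
06,0.590,2.615,1001.42,5096.65,0.290,0.331,0.343,0.354,0.415
07,0.262,1.518,964.59,7270.17,0.343,0.349,0.370,0.424,0.480
08,0.324,2.676,704.42,4091.19,0.216,0.243,0.340,0.371,0.433
09,0.356,0.891,958.55,9282.78,0.366,0.555,0.559,0.602,0.605
10,0.089,2.557,851.70,4588.62,0.199,0.207,0.298,0.391,0.396
11,0.243,0.925,1006.45,4610.27,0.384,0.385,0.533,0.615,0.652
12,1.003,1.409,932.51,6127.49,0.528,0.541,0.567,0.581,0.631
13,0.057,0.879,647.98,4017.69,0.198,0.369,0.428,0.506,0.583
14,0.762,0.460,1081.34,8260.98,0.639,0.743,0.767,0.787,0.845
15,0.344,2.132,939.61,6778.40,0.289,0.334,0.387,0.397,0.408
16,0.141,1.661,753.24,7102.67,0.226,0.339,0.349,0.350,0.379
17,0.470,0.544,900.53,5832.50,0.514,0.541,0.691,0.705,0.758
18,0.525,0.631,841.61,4872.18,0.529,0.661,0.689,0.695,0.847
19,0.423,1.525,786.47,5109.69,0.393,0.401,0.451,0.512,0.540
20,0.661,2.798,765.99,8486.20,0.328,0.334,0.341,0.342,0.360
21,0.686,1.943,908.60,5725.97,0.345,0.389,0.404,0.408,0.463
22,0.613,3.142,893.06,5438.46,0.278,0.303,0.305,0.337,0.342
23,0.421,1.528,695.05,4989.05,0.318,0.502,0.518,0.533,0.563
24,0.863,2.078,768.83,6182.47,0.435,0.454,0.469,0.476,0.479
25,0.414,1.172,687.85,5733.62,0.408,0.559,0.575,0.600,0.625
26,0.635,0.836,925.62,6168.52,0.659,0.681,0.682,0.708,0.746
27,0.952,1.596,869.00,6351.31,0.440,0.444,0.466,0.490,0.555
28,0.805,1.486,809.18,5987.13,0.472,0.497,0.507,0.527,0.551
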