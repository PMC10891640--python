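compound,k1_1e-4_s-1,sd_k1_1e-4_s-1,k2_1e-4_s-1,sd_k2_1e-4_s-1,r2_percent,t01_min,lof_percent
DA1,4.435,0.107,0.389,0.013,99.89,4.134,3.281
DA2,12.31,0.494,1.771,0.060,99.73,1.491,5.153
DA3,1.217,0.022,,,99.93,15.064,2.693
DA4,1.226,0.020,,,99.77,14.954,4.758
DA5,140.4,6.183,,,99.17,0.131,6.085
DA6,1.597,0.071,,,99.57,11.483,6.553
DA7,1.345,0.012,,,99.96,13.633,1.963
DA8,4.322,0.091,,,99.96,4.242,2.105
DA9,1.061,0.005,,,99.99,17.273,0.919
DA10,18.48,0.775,,,99.36,0.992,6.981
DA11,1.315,0.016,,,99.94,13.939,2.406
DA12,1.389,0.009,,,99.99,13.204,0.999
DHP1,392.4,7.800,,,99.95,1.171,1.910
DHP5,376.3,4.900,,,99.89,1.220,1.730
DHP6,208.0,5.000,,,99.87,2.200,2.550
DHP7,91.00,1.900,,,99.67,5.030,1.751
DHP9,143.3,4.300,,,99.83,3.190,2.392
DHP10,222.3,8.100,,,99.58,2.060,2.251
DHP11,223.5,8.900,,,99.64,2.051,1.751
DHP12,81.30,1.800,,,99.78,5.631,1.232
HM8,101.0,4.798,2.354,0.070,99.71,0.182,5.341
HM10,1.918,0.060,0.752,0.032,99.94,9.562,2.456
HM13,0.950,0.300,,,99.94,19.329,2.512
HM14,22.77,0.501,,,99.97,0.805,3.643
HM15,1.494,0.039,,,99.32,12.274,6.263
HM16,56.28,1.262,0.781,0.013,99.95,0.326,2.199
MD20,78.12,2.442,2.335,0.050,99.84,0.235,4.035
M3,2.642,0.030,1.271,0.017,99.97,6.940,1.836
NICA,6.044,0.211,,,99.84,3.030,3.941
NIMO,8.290,0.494,8.290,0.762,99.98,2.211,1.501
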