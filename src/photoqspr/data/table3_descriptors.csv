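compound,role,ALogP,AATSC5m,MATS5c,MATS4s,GATS5m,SCH-6,VCH-5,minHBd,minHBint7,nAtomLC,nFRing,nT10HeteroRing,RDF40m,RDF45m,RDF85m,RDF115e,E3m
DA1,calibration,0.895,0.5349,-0.0763,-0.091,0.960,0.328,0.029,0.277,1.541,7,2,1,12.672,13.082,6.3882,5.3440,0.219
DA2,calibration,1.784,12.455,-0.1343,-0.092,0.928,0.316,0.029,0.266,1.500,7,2,1,23.441,14.137,6.3882,5.3440,0.468
DA3,calibration,1.198,0.6475,-0.1391,-0.070,0.995,0.279,0,0.252,0,7,1,1,12.991,12.828,8.4192,11.175,0.108
DA4,calibration,1.198,0.3788,-0.1377,-0.071,1.005,0.279,0,0.255,0,7,1,1,12.987,11.390,10.488,15.520,0.172
DA5,calibration,0.531,1.0708,-0.3468,-0.070,0.966,0.232,0,0.287,0,7,2,2,18.319,12.670,5.6093,7.2459,0.244
DA6,calibration,1.721,7.3378,-0.0287,-0.071,0.914,0.177,0.118,0.262,0,7,1,1,14.711,8.9512,5.1640,5.3099,0.201
DA7,calibration,1.198,1.0262,-0.2355,-0.079,0.991,0.196,0,0.279,0,7,1,1,11.716,11.609,4.6429,5.3100,0.179
DA8,calibration,1.198,0.7416,-0.1399,-0.074,0.996,0.245,0,0.257,0,7,2,1,11.954,11.300,6.8782,5.4597,0.190
DA9,calibration,1.198,1.1070,-0.1436,-0.070,1.001,0.196,0,0.269,0,7,1,1,11.656,11.066,4.8526,5.3092,0.129
DA10,calibration,1.588,-2.2961,-0.2223,-0.119,1.087,0.104,0,0.307,0,7,1,1,8.6260,4.6878,3.0658,5.3097,0.051
DA11,calibration,1.211,-0.0733,-0.0964,-0.074,0.997,0.260,0.039,0.264,0,7,1,1,12.545,14.596,10.913,9.0331,0.154
DHP1,calibration,2.151,-6.9717,-0.4033,0.094,1.013,0.264,0,0.248,0.183,4,1,1,31.851,23.834,9.9394,4.3322,0.366
DHP6,calibration,2.113,1.0891,-0.3044,-0.084,0.869,0.264,0,0.261,0.191,4,1,1,33.429,25.382,8.1966,7.1145,0.364
DHP11,calibration,0.884,-3.0051,-0.3548,-0.033,0.939,0.284,0,0.288,0.215,4,1,1,31.568,23.373,7.8238,4.0094,0.386
HM10,calibration,2.728,-0.5443,-0.0922,-0.184,0.850,0.149,0,0.268,0.121,11,1,1,26.156,19.072,14.842,13.939,0.379
HM13,calibration,2.872,-3.5382,-0.0939,-0.181,0.791,0.149,0,0.266,0.163,11,1,1,22.243,15.955,22.571,11.192,0.322
HM14,calibration,2.788,7.1796,-0.0891,-0.092,0.941,0.149,0,0.308,1.532,11,1,1,21.555,19.234,13.523,11.140,0.306
HM15,calibration,2.788,2.2566,-0.1016,-0.183,0.988,0.149,0,0.291,1.532,11,1,1,20.069,13.500,19.511,14.199,0.256
HM16,calibration,2.559,1.2276,-0.1192,-0.119,0.880,0.149,0,0.336,1.648,11,1,1,23.994,21.070,11.162,14.199,0.323
NIMO,calibration,0.727,-4.1293,-0.1769,-0.095,1.057,0.129,0,0.390,1.906,7,0,0,16.456,15.744,4.2296,6.2738,0.111
DA12,prediction,1.211,-0.4667,-0.1001,-0.078,0.997,0.260,0.029,0.269,0,7,1,1,12.708,12.200,10.202,14.360,0.175
DHP5,prediction,2.505,-5.7584,-0.2736,0.013,1.016,0.264,0,0.285,0,4,1,1,35.806,22.011,12.323,5.1042,0.271
DHP7,prediction,1.849,0.5783,-0.3282,-0.106,0.882,0.264,0,0.292,0.092,4,1,1,22.168,18.126,8.0499,7.1145,0.342
DHP9,prediction,2.203,1.4613,-0.2254,0.062,0.873,0.264,0,0.329,0,4,1,1,17.679,16.303,10.610,7.8853,0.253
DHP10,prediction,2.467,1.9612,-0.2013,-0.082,0.861,0.264,0,0.298,0,4,1,1,37.457,23.559,10.756,7.8853,0.258
DHP12,prediction,0.619,-3.2561,-0.3772,-0.087,0.954,0.284,0,0.319,0.105,4,1,1,21.045,16.118,7.6773,4.0094,0.359
HM8,prediction,1.485,4.3519,-0.2163,-0.054,0.832,0.251,0,0.321,0,4,1,1,24.438,19.468,13.238,10.310,0.343
M3,prediction,0.825,3.5196,-0.2307,-0.114,0.874,0.264,0,0.302,0,4,1,1,17.510,12.141,7.5004,6.4756,0.302
MD20,prediction,2.058,3.0868,-0.2009,-0.043,0.838,0.149,0,0.316,0,7,1,1,22.172,15.548,8.1647,5.3099,0.418
NICA,prediction,0.906,-3.4479,-0.2082,-0.037,1.091,0.231,0,0.364,0.741,8,0,0,19.970,15.665,9.4702,10.748,0.115
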