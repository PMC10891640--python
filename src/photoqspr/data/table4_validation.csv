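compound,role,k_exp_1e-3_s-1,k_pred_1e-3_s-1,error_percent
DA1,calibration,0.443,0.452,1.878
DA2,calibration,1.231,1.226,-0.400
DA3,calibration,0.122,0.120,-1.215
DA4,calibration,0.123,0.129,4.884
DA5,calibration,14.042,14.043,0.007
DA6,calibration,0.160,0.161,0.632
DA7,calibration,0.134,0.136,0.788
DA8,calibration,0.432,0.429,-0.788
DA9,calibration,0.106,0.097,-9.039
DA10,calibration,1.848,1.852,0.221
DA11,calibration,0.132,0.126,-4.333
DHP1,calibration,39.240,39.239,-0.002
DHP6,calibration,20.800,20.801,0.006
DHP11,calibration,22.350,22.351,0.005
HM10,calibration,0.192,0.197,2.814
HM13,calibration,0.095,0.095,0.299
HM14,calibration,2.277,2.292,0.623
HM15,calibration,0.149,0.143,-4.165
HM16,calibration,5.628,5.616,-0.221
NIMO,calibration,0.829,0.830,0.118
DA12,prediction,0.139,0.135,-2.704
DHP5,prediction,37.630,35.454,-5.783
DHP7,prediction,9.100,9.683,6.403
DHP9,prediction,14.330,15.072,5.179
DHP10,prediction,22.230,22.264,0.154
DHP12,prediction,8.130,8.770,7.876
HM8,prediction,10.099,10.365,2.635
M3,prediction,0.264,0.228,-13.662
MD20,prediction,7.812,7.978,2.123
NICA,prediction,0.604,0.640,5.813
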