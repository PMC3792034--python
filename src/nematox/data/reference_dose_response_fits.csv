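series_id,species,family,p1,p2,p3,p4,y_target,search_max,reported_lc50,reported_r_squared
WB_Ce,C_elegans,quadratic,5e-07,-0.0049,10.426,,5,11490,1272.60,0.9754
WB_Ce,C_elegans,cubic,2e-10,-1e-06,-0.0014,9.6338,5,11490,1813.16,0.9965
WB_Ce,C_elegans,logarithmic,-2.314,20.796,,,5,11490,921.75,0.8291
WB_Ce,C_elegans,exponential_shifted,8.8914,-0.0003,,,5,11490,1311.08,0.7106
WB_Pp,P_pacificus,quadratic,4e-07,-0.004,7.9846,,4,11490,1122.05,0.9326
WB_Pp,P_pacificus,cubic,-1e-11,5e-07,-0.0042,8.0417,4,11490,1104.27,0.9328
WB_Pp,P_pacificus,logarithmic,-1.919,16.753,,,4,11490,769.43,0.8935
WB_Pp,P_pacificus,exponential_shifted,6.8283,-0.0003,,,4,11490,1038.79,0.7016
SR_Pp,P_pacificus,quadratic,2e-05,-0.0224,6.9736,,3,1411.5,221.00,0.965
SR_Pp,P_pacificus,cubic,2e-08,-2e-05,-0.0132,6.572,3,1411.5,215.43,0.9756
SR_Pp,P_pacificus,logarithmic,-1.563,11.008,,,3,1411.5,167.92,0.8093
SR_Pp,P_pacificus,exponential_shifted,6.5431,-0.002,,,3,1411.5,246.06,0.7625
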