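treatment_id,sediment_id,spike_level,medium,tr_ni,pw_ni,toc,avs,cec,ph,orp,clay,silt,sand,log_kd
WB-0,WB,0,sediment,59.7,0.93,10.40,38,44.1,6.63,-87,24.7,68.3,7.0,4.56
WB-1,WB,1,sediment,156,4.62,11.20,25,42.5,6.62,-79,21.1,66.1,12.8,4.37
WB-2,WB,2,sediment,369,8.57,9.70,26,37.4,6.65,-85,20.6,66.5,12.9,4.24
WB-3,WB,3,sediment,1040,26.0,11.20,26,44.7,6.65,-89,24.8,63.6,11.6,4.20
WB-4,WB,4,sediment,2680,98.1,10.50,18,39.7,6.62,-86,21.0,63.5,15.5,4.13
WB-5,WB,5,sediment,7660,122,10.20,12,37.4,6.65,-80,23.5,66.3,10.2,3.92
SR-0,SR,0,sediment,8.9,1.70,0.40,0.94,5.5,7.03,-169,6.9,13.6,79.5,3.56
SR-1,SR,1,sediment,56.6,11,0.60,0.90,6.4,6.96,-171,7.9,15.7,76.4,3.56
SR-2,SR,2,sediment,122,67.7,0.40,0.77,5.0,7.03,-165,7.1,12.7,80.2,3.55
SR-3,SR,3,sediment,213,164,0.40,0.70,6.3,7.03,-162,8.4,13.9,77.7,3.55
SR-4,SR,4,sediment,411,801,0.30,0.51,5.0,7.06,-156,8.1,12.2,79.7,3.57
SR-5,SR,5,sediment,941,5700,0.40,0.46,5.4,7.03,-152,7.9,14.2,77.9,3.57
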