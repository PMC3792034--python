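treatment_id,sediment_id,spike_level,medium,tr_ni,pw_ni,toc,avs,cec,ph,orp,clay,silt,sand,log_kd
SR,SR,0,sediment,8.9,,0.40,0.94,5.5,7.03,-169,6.9,13.6,79.5,3.56
STJ,STJ,0,sediment,8,,1.9,3.78,11.3,7.28,-186,7.9,10.3,81.8,3.979
P30,P30,0,sediment,14,,1.8,12.37,19.0,6.87,-168,24.2,66.0,9.8,4.248
DOW,DOW,0,sediment,6,,1.2,1.04,6.4,6.90,-155,6.0,7.0,87.0,3.794
RR2,RR2,0,sediment,12,,3.5,6.06,14.5,6.98,-188,8.1,19.8,72.1,4.164
STM,STM,0,sediment,18,,8.1,24.70,29.1,7.14,-189,8.4,37.5,54.1,4.349
RR3,RR3,0,sediment,9,,7.2,7.98,29.3,7.02,-179,5.9,19.5,74.6,3.857
WB,WB,0,sediment,59.7,,10.40,38,44.1,6.63,-87,24.7,68.3,7.0,4.56
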