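treatment_id,p1,p2,p3,p4,day_max,reported_lt50,reported_r_squared
WB-0,0.0001,-0.0056,0.0347,0.8407,22,14.052,0.7985
WB-2,-0.0003,0.0108,-0.1324,1.1398,22,18.172,0.7651
WB-3,0.0001,-0.0014,-0.0633,1.0282,22,7.751,0.8995
WB-5,-0.0004,0.0158,-0.2272,1.0489,22,2.991,0.9702
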