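treatment,DOC,Cl,F,NO3,SO4,Ca,Fe,K,Mg,Mn,Na
SR,7,16.7,0.4,<0.08,<0.08,118,9.0,5.6,8.7,10.0,10
STJ,32,40,0.9,7.7,18.2,237,10,4.9,67,10,22
P30,21,20,<0.08,6.6,<0.08,182,46,7.0,52,6,22
DOW,51,79,<0.08,<0.08,<0.08,271,35,7.2,61,8,26
RR2,21,19,0.9,7.2,<0.08,189,21,4.4,47,5,10
STM,47,85,<0.08,<0.08,<0.08,348,35,10.0,70,4,26
RR3,32,27,<0.08,5,<0.08,192,29,4.3,43,7,16
WB,30,18.8,0.4,<0.08,80,26,18.0,2.0,6.9,2.9,6.6
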