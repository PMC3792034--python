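sample,Al,Ba,Ca,Cr,Fe,K,Mg,Mn,Na,Sr,V,Zn
SR,12556,,1481,,7753,1598,488,215,,,,54.9
STJ,7212,72,6731,14,22260,962,1875,529,<1000,16,19,39
P30,28947,158,34450,33,16268,2392,3206,292,<1000,86,48,46
DOW,6965,39,3682,10,6468,995,1692,119,995,17,16,40
RR2,7000,70,56500,15,10700,1500,7000,425,<1000,50,20,45
STM,10784,172,85784,15,24755,2745,12892,637,<1000,162,28,64
RR3,5238,95,54762,10,14429,476,7000,905,<1000,110,14,43
WB,24707,,4546,,51317,5957,5368,678,,,,141.1
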