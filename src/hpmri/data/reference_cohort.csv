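tumour,FinalGleason,ISUP,pctGP4,meanADC,lactateSNR,pyruvateSNR,totalCarbonSNR,meanKPL,excluded_from_correlation
1,3+4=7,2,<5,1239.0,8,33,49,0.015,0
2,3+4=7,2,<5,1380.0,9,37,53,0.012,0
3,3+4=7,2,10,921.5,11,69,87,0.009,0
4,4+3=7,3,60,788.7,16,70,89,0.015,0
5,3+4=7,2,5,743.6,12,21,39,0.014,0
6,3+3=6,1,0,1074.0,6,19,27,0.011,0
7,3+4=7,2,15,845.0,15,22,37,0.004,0
8,3+4=7,2,30,721.0,14,26,51,0.005,0
9,3+4=7,2,20,1060.0,16,47,77,0.006,0
10,3+4=7,2,<5,763.1,40,68,112,0.018,0
11,3+4=7,2,<5,923.3,10,15,29,0.003,0
12,4+3=7,3,50,581.5,24,36,62,0.015,0
13,3+3=6,1,0,762.0,8,31,54,0.009,1
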