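patient,age,sex,injected_activity_MBq,t1_h,t2_h,t3_h,tumor_volume_mL,liver_volume_mL
1,64,M,3405,2.7,26.3,50.3,131,1012
2,69,M,6013,3.6,27.8,,240,1200
3,33,M,7162,5.2,27.5,52.6,1000,4030
4,59,M,1296,1.3,27.7,,22,1194
5,71,M,1527,4.6,27.3,,10,975
6,46,F,1750,3.1,24.7,49.2,400,1300
7a,20,F,5239,4.2,29.1,,600,1400
7b,20,F,5559,3.6,28.2,51.3,150,1400
8,51,M,2479,3.0,26.6,42.8,11,1260
9,53,M,2444,1.6,25.4,47.0,65,1300
10,72,M,2284,5.5,26.5,56.1,10,1300
11,68,M,1722,2.6,27.0,51.4,90,1152
12,62,M,2602,3.8,27.4,49.8,340,1200
13,71,M,1637,3.8,24.9,44.7,2.3,800
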