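# config=52e42e78a2e6
nucleus_id,start_s,end_s,peak
1,235.20000000000002,487.20000000000005,5129.299014544367
3,151.20000000000002,252.0,695.1517191268644
3,319.2,487.20000000000005,4335.338187829893
4,67.2,168.0,3625.4519008531765
5,302.40000000000003,453.6,2782.1377690173276
6,218.4,420.0,4846.1340112542875
7,84.0,268.8,4659.58655896526
8,33.6,168.0,3679.224897122656
8,252.0,470.40000000000003,5028.940481303868
9,134.4,352.8,2785.6082781037235
10,33.6,100.80000000000001,2275.895575051481
10,302.40000000000003,436.8,4284.703787549517
11,218.4,336.0,4419.088015068495
11,352.8,487.20000000000005,4987.367889777085
15,100.80000000000001,168.0,578.2247068676841
16,117.60000000000001,487.20000000000005,5124.077182434114
17,33.6,100.80000000000001,735.9081640841744
17,184.8,336.0,3807.9381428229126
17,386.40000000000003,487.20000000000005,784.4435790316923
18,403.20000000000005,487.20000000000005,1292.5195622526583
19,100.80000000000001,403.20000000000005,4262.281470343489
20,33.6,302.40000000000003,4518.642144098162
20,352.8,453.6,580.7092807462177
21,117.60000000000001,218.4,3433.7443642871413
22,100.80000000000001,201.60000000000002,1975.366884107126
23,168.0,369.6,4451.656572748497
24,168.0,386.40000000000003,4918.844047192926
25,218.4,436.8,5274.676762485239
26,252.0,487.20000000000005,5177.477558742762
27,50.400000000000006,184.8,3269.4169896416597
27,201.60000000000002,352.8,1202.3655599051024
28,201.60000000000002,302.40000000000003,4617.435279415707
29,285.6,436.8,4369.127706093468
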