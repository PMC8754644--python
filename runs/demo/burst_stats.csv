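# config=52e42e78a2e6
nucleus_id,n_bursts,amplitude,duration,total_output,t_first,induction_rate
1,1,5129.299014544367,268.8,1101216.2030004375,235.20000000000002,0.23809523809523808
2,0,,,81664.67607053644,,
3,2,2515.2449534783786,151.20000000000002,590183.0690682608,151.20000000000002,0.3571428571428571
4,1,3625.4519008531765,117.60000000000001,355292.2976242655,67.2,0.14285714285714285
5,1,2782.1377690173276,168.0,368291.9603049214,302.40000000000003,0.3246753246753247
6,1,4846.1340112542875,218.4,935691.0919284753,218.4,0.22321428571428564
7,1,4659.58655896526,201.60000000000002,742549.2576658946,84.0,0.1488095238095238
8,2,4354.082689213262,193.20000000000002,1253140.6642024452,33.6,0.26455026455026454
9,1,2785.6082781037235,235.20000000000002,508877.82044150826,134.4,0.17006802721088432
10,2,3280.2996813004993,117.60000000000001,540567.4749335742,33.6,0.26455026455026454
11,2,4703.227952422791,142.8,963894.5243371594,218.4,0.4464285714285713
12,0,,,100446.6468296064,,
13,0,,,348970.32271338656,,
14,0,,,105490.73531445627,,
15,1,578.2247068676841,84.0,140814.90873879375,100.80000000000001,0.15527950310559005
16,1,5124.077182434114,386.40000000000003,1618593.063825994,117.60000000000001,0.16233766233766234
17,3,1776.0966286462597,123.2,447490.46552728873,33.6,0.3968253968253968
18,1,1292.5195622526583,100.80000000000001,161273.1127856057,403.20000000000005,0.7142857142857142
19,1,4262.281470343489,319.2,829955.1480314618,100.80000000000001,0.15527950310559005
20,2,2549.67571242219,201.60000000000002,630243.5421144142,33.6,0.26455026455026454
21,1,3433.7443642871413,117.60000000000001,542332.2411948672,117.60000000000001,0.16233766233766234
22,1,1975.366884107126,117.60000000000001,215687.38936617816,100.80000000000001,0.15527950310559005
23,1,4451.656572748497,218.4,788491.8804122752,168.0,0.18796992481203004
24,1,4918.844047192926,235.20000000000002,713786.9475387892,168.0,0.18796992481203004
25,1,5274.676762485239,235.20000000000002,955954.6590071573,218.4,0.22321428571428564
26,1,5177.477558742762,252.0,1077073.3806714849,252.0,0.2551020408163265
27,2,2235.891274773381,159.60000000000002,393327.3422732637,50.400000000000006,0.2747252747252747
28,1,4617.435279415707,117.60000000000001,495837.0576234169,201.60000000000002,0.21008403361344535
29,1,4369.127706093468,168.0,554788.3365023633,285.6,0.2976190476190476
30,0,,,135945.22707713651,,
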