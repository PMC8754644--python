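# config=52e42e78a2e6
frame,time_s,inst_fraction,cum_fraction,mean_active,sd_active
0,0.0,0.1,0.1,1848.5263146160114,739.2688341004343
1,16.8,0.16666666666666666,0.16666666666666666,1510.1439487411258,722.0877779056954
2,33.6,0.26666666666666666,0.26666666666666666,1277.5719662063818,522.275332599967
3,50.400000000000006,0.26666666666666666,0.4,1153.6864919350423,600.8950790199074
4,67.2,0.2,0.4,1968.7936385076753,912.6329845500128
5,84.0,0.3,0.5333333333333333,2402.2452197228063,1604.277944097993
6,100.80000000000001,0.3,0.6,2668.3382057164863,1581.3412352881894
7,117.60000000000001,0.36666666666666664,0.6333333333333333,2443.7888943617436,1416.98646346936
8,134.4,0.3333333333333333,0.6333333333333333,2435.8020658182822,785.7419786381407
9,151.20000000000002,0.3333333333333333,0.6666666666666666,2677.4735227479323,1347.0146047699861
10,168.0,0.4,0.7,2629.19821534664,1641.5662592901176
11,184.8,0.5,0.7666666666666667,2292.1831926890677,1608.4895606311297
12,201.60000000000002,0.4666666666666667,0.8,2423.1788620335487,1634.4784407211666
13,218.4,0.5,0.8666666666666667,2744.3044040987156,1521.187264990268
14,235.20000000000002,0.4666666666666667,0.8666666666666667,3362.6200878192517,1539.5547694832214
15,252.0,0.5333333333333333,0.9,3103.9154272826,1164.4669660770303
16,268.8,0.5666666666666667,0.9333333333333333,3490.6225339464063,1346.9837463130773
17,285.6,0.7,0.9333333333333333,2894.5967449684413,1535.1721043114019
18,302.40000000000003,0.6333333333333333,0.9333333333333333,3345.3844143180163,1918.7306413290655
19,319.2,0.5333333333333333,0.9333333333333333,3660.3357943839023,1674.1309315444691
20,336.0,0.4666666666666667,0.9333333333333333,3787.4877892414124,1504.329480657874
21,352.8,0.4666666666666667,0.9666666666666667,3543.883785215524,1366.8340696042455
22,369.6,0.5333333333333333,0.9666666666666667,3318.977190786897,1661.7576033959647
23,386.40000000000003,0.5333333333333333,0.9666666666666667,3229.799813361938,1550.2967890197453
24,403.20000000000005,0.5,0.9666666666666667,3046.0769580217016,1463.269860346903
25,420.0,0.43333333333333335,1.0,2968.0887454749604,1711.0790871585646
26,436.8,0.5,1.0,2494.784608707627,1391.094235900714
27,453.6,0.4,1.0,2782.755510684629,1096.3186357621257
28,470.40000000000003,0.43333333333333335,1.0,2487.9184405305236,1401.2047632115073
29,487.20000000000005,0.36666666666666664,1.0,3165.7266107428395,1729.5125075902831
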