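# config=52e42e78a2e6
nucleus_id,t_start_s,t_end_s
1,179.60115598769937,184.7160162504455
2,82.37071490845403,87.56985168307335
2,223.59344576928228,369.06560326767595
2,390.64221971865686,432.4130267847116
3,92.08438045528736,157.75990036013778
3,413.2449670402233,504.0
4,205.79022436683584,212.81263067841746
4,337.63819151990043,504.0
5,98.51816863890967,412.0586847571517
6,119.97657620117377,154.03270026664615
6,200.71469149717697,277.91660584483225
6,376.5028933850657,380.0323118212855
6,493.41913933205944,504.0
7,9.263796026126201,30.51895967007329
7,105.97640837309446,240.46356127623778
8,159.2510609269233,167.25032190466428
8,291.4380330797338,376.316456121637
8,433.12336345983306,438.1871577251179
9,263.54600013356634,272.4735810340074
9,366.96765267402736,392.4707603968407
10,109.15680737787396,133.5619539725759
10,161.52182773744508,333.91243509929285
10,486.25929174810176,504.0
11,125.892745251924,306.027364313749
11,392.63387307336467,405.46498173736705
13,289.98864543565924,294.61915443028215
13,498.86443725504387,504.0
14,144.51193314823908,177.20657294758854
14,222.33111914925902,306.21617978471727
14,499.55162961553276,504.0
15,53.3107862801925,97.49233208618617
16,399.39087831169286,503.27430024131536
17,189.1107775608312,274.0310871979965
17,352.287861545001,504.0
18,90.01058220568959,107.86275767409833
18,292.21448426332915,293.47290645814223
18,448.1028112359223,504.0
19,164.1794994581394,241.78813701447112
20,265.5290856835475,384.1516381318354
21,21.777077123117987,56.626776512069114
21,277.92518470375524,367.1626023556995
22,22.047557125109623,88.60093772748225
22,230.29061074701556,413.6678136075415
23,36.95908072842739,52.4551341167895
23,168.80577786163337,375.05008408542386
24,204.79985315782002,211.94124550153714
24,298.30690337249774,304.5041768447397
25,40.39889956110061,42.795441733023736
25,181.6601593157643,261.9627592925207
25,317.2568456370268,328.1818291874404
25,478.34943076646874,504.0
26,26.498835277542064,47.82033580470888
26,53.24829911528317,124.38253604596366
26,130.56451441262527,182.5653360566323
26,210.72285036035302,242.07061761167148
27,231.5526050835594,457.3577312682758
28,31.2202675192807,104.36619675453315
29,28.715313705230024,104.01382750324518
29,214.61551044547596,247.06428658652132
30,13.915921122565098,30.76869792363853
30,145.20852717366122,146.65646650957444
30,198.66438679220985,420.919141778054
30,454.3837656298117,504.0
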