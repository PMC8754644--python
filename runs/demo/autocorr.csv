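# config=52e42e78a2e6
lag_s,mean_ac,null_ac
0.0,1.0,1.0
16.8,0.7479735156023715,-0.015439725307319484
33.6,0.4933281867934772,-0.06902614399019222
50.400000000000006,0.19215919710587773,-0.009767315881264982
67.2,-0.06033615017026932,-0.06728220410905442
84.0,-0.2617273532721575,-0.07649197867323171
100.80000000000001,-0.24324096230542747,-0.026043980801347663
117.60000000000001,-0.20231140257475078,-0.029656087547112023
134.4,-0.1581044881535788,0.00860693526811694
151.20000000000002,-0.13416211885448262,-0.006914912998367575
168.0,-0.1315508225425937,7.41793916689887e-05
184.8,-0.1271401632689124,-0.029157789182875402
201.60000000000002,-0.1362141012000353,0.012723903325569835
218.4,-0.11815406076251823,0.023718889692794544
235.20000000000002,-0.10344086853280757,-0.03315161887934434
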