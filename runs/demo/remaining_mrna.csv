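# config=52e42e78a2e6
final_label,remaining
1,62320.73422921088
2,519185.8526150722
3,883934.5166748057
4,440357.1873213013
5,290405.0911988049
6,507310.5933189436
7,888394.955545558
8,220773.14608816267
9,904813.4133538525
10,320793.5407299274
11,67614.83478352976
12,106785.7491131749
13,390194.5902389285
14,329338.211296802
15,784182.4184862087
16,121642.89189703835
17,696402.9019580238
18,436863.25301224913
19,72939.71842680646
20,192340.75764651332
21,586182.8631259445
22,398606.19289572525
23,403170.1461188818
24,330377.2059057466
25,544690.3971470641
26,100210.6660724604
27,747862.0607258942
28,1188338.0350062873
29,119069.73853196709
30,310376.5745198641
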