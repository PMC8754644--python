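# config=52e42e78a2e6
frame,n_labels,threshold,method
0,30,0.337890625,method-1
1,30,0.337890625,method-1
2,30,0.337890625,method-1
3,30,0.337890625,method-1
4,30,0.337890625,method-1
5,30,0.333984375,method-1
6,30,0.337890625,method-1
7,30,0.337890625,method-1
8,30,0.337890625,method-1
9,30,0.337890625,method-1
10,30,0.337890625,method-1
11,30,0.337890625,method-1
12,30,0.337890625,method-1
13,30,0.337890625,method-1
14,30,0.337890625,method-1
15,30,0.337890625,method-1
16,30,0.337890625,method-1
17,30,0.337890625,method-1
18,30,0.337890625,method-1
19,30,0.337890625,method-1
20,30,0.341796875,method-1
21,30,0.337890625,method-1
22,30,0.337890625,method-1
23,30,0.337890625,method-1
24,30,0.341796875,method-1
25,30,0.341796875,method-1
26,30,0.341796875,method-1
27,30,0.341796875,method-1
28,30,0.341796875,method-1
29,30,0.341796875,method-1
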