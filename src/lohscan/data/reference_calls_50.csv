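sample_id,D15S118,D15S214,D15S1006,D17S855,D17S1323,D13S260,D13S290
1,ni,ni,ni,NG,NG,NG,ni
2,NG,NG,NG,ni,NG,ni,NG
3,ni,ni,ni,NG,ni,LOH,LOH
4,NG,LOH,NG,ni,ni,ni,ni
5,ni,LOH,NG,NG,ni,NG,NG
6,ni,ni,NG,ni,ni,NG,LOH
7,ni,LOH,ni,ni,NG,ni,ni
8,NG,LOH,LOH,ni,NG,ni,ni
9,ni,ni,NG,ni,ni,NG,ni
10,NG,ni,ni,ni,ni,ni,NG
11,NG,ni,ni,ni,ni,NG,ni
12,ni,LOH,ni,ni,NG,LOH,ni
13,NG,NG,ni,NG,ni,LOH,ni
14,ni,ni,ni,NG,ni,ni,ni
15,ni,ni,ni,NG,ni,ni,NG
16,NG,ni,ni,ni,ni,ni,ni
17,NG,ni,ni,ni,ni,LOH,ni
18,ni,ni,LOH,ni,ni,LOH,ni
19,LOH,LOH,ni,ni,NG,ni,ni
20,ni,ni,ni,NG,ni,NG,ni
21,ni,NG,ni,ni,ni,ni,LOH
22,ni,ni,ni,ni,ni,NG,NG
23,NG,LOH,ni,ni,NG,NG,ni
24,NG,LOH,ni,ni,ni,LOH,ni
25,LOH,LOH,ni,LOH,ni,LOH,ni
26,NG,LOH,ni,ni,ni,ni,NG
27,NG,ni,ni,LOH,NG,ni,ni
28,LOH,NG,ni,LOH,ni,ni,ni
29,ni,LOH,ni,ni,ni,ni,ni
30,ni,ni,ni,NG,ni,ni,NG
31,LOH,ni,ni,NG,ni,LOH,LOH
32,LOH,ni,LOH,NG,ni,ni,ni
33,LOH,NG,ni,ni,ni,ni,ni
34,LOH,LOH,ni,NG,ni,NG,NG
35,LOH,NG,ni,LOH,ni,NG,LOH
36,ni,ni,ni,ni,ni,NG,NG
37,NG,ni,ni,NG,NG,ni,ni
38,NG,ni,ni,ni,NG,NG,LOH
39,ni,ni,ni,ni,LOH,NG,ni
40,ni,LOH,ni,ni,NG,ni,ni
41,NG,LOH,NG,LOH,NG,NG,ni
42,ni,NG,ni,ni,ni,NG,NG
43,ni,NG,ni,NG,ni,NG,NG
44,ni,LOH,ni,ni,ni,ni,ni
45,ni,NG,LOH,ni,ni,NG,LOH
46,ni,ni,NG,ni,ni,ni,ni
47,ni,ni,ni,ni,ni,NG,NG
48,LOH,ni,ni,NG,LOH,ni,LOH
49,ni,NG,NG,ni,NG,NG,ni
50,ni,ni,NG,NG,NG,ni,NG
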