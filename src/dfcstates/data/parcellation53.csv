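roi_index,roi_label,network
0,SC_01,SC
1,SC_02,SC
2,SC_03,SC
3,SC_04,SC
4,SC_05,SC
5,AUD_01,AUD
6,AUD_02,AUD
7,SM_01,SM
8,SM_02,SM
9,SM_03,SM
10,SM_04,SM
11,SM_05,SM
12,SM_06,SM
13,SM_07,SM
14,SM_08,SM
15,SM_09,SM
16,VS_01,VS
17,VS_02,VS
18,VS_03,VS
19,VS_04,VS
20,VS_05,VS
21,VS_06,VS
22,VS_07,VS
23,VS_08,VS
24,VS_09,VS
25,CC_01,CC
26,CC_02,CC
27,CC_03,CC
28,CC_04,CC
29,CC_05,CC
30,CC_06,CC
31,CC_07,CC
32,CC_08,CC
33,CC_09,CC
34,CC_10,CC
35,CC_11,CC
36,CC_12,CC
37,CC_13,CC
38,CC_14,CC
39,CC_15,CC
40,CC_16,CC
41,CC_17,CC
42,DM_01,DM
43,DM_02,DM
44,DM_03,DM
45,DM_04,DM
46,DM_05,DM
47,DM_06,DM
48,DM_07,DM
49,CB_01,CB
50,CB_02,CB
51,CB_03,CB
52,CB_04,CB
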