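patient,birads_density,age,history_pregnancy,history_breastfeeding,family_history_breast_cancer
1,B,72,Yes,No,Yes
2,B,68,Yes,Yes,Yes
3,B,72,Yes,Yes,Unknown
4,C,64,Yes,Yes,No
5,C,50,Yes,Yes,No
6,B,60,Yes,Unknown,Unknown
7,B,65,Yes,Yes,No
8,B,61,Yes,Yes,Yes
9,B,60,No,No,Yes
10,C,67,Yes,Yes,Yes
11,C,40,Yes,Yes,No
12,B,47,Yes,No,Yes
13,B,50,Yes,Yes,No
14,C,50,No,No,Yes
15,C,44,No,No,Yes
16,B,52,Yes,Yes,No
17,C,48,Yes,Yes,No
18,C,46,Yes,Yes,Yes
19,C,66,Yes,Yes,No
20,C,60,Yes,Yes,Yes
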