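patient_id,area_fully_resected,ilae
1,0,3
2,0,4
3,1,1
4,1,1
5,1,1
6,0,3
7,0,5
8,0,1
9,1,1
10,1,1
11,0,1
12,0,5
13,1,1
14,1,1
15,1,1
16,1,1
17,0,3
18,0,1
19,1,1
20,1,1
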