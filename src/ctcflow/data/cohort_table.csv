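case,ctc_count,ctc_her2_intensity,ctc_her2_status,emt_index,tissue_her2
1,2,45,negative,0.15,negative
2,12,44,negative,0.15,negative
3,1,26,negative,0.14,negative
4,39,133,positive,0.17,negative
5,2,186,positive,0.18,negative
6,7,71,positive,0.17,negative
7,29,41,negative,0.15,negative
8,20,41,negative,0.16,negative
9,7,44,negative,0.15,negative
10,9,131,positive,0.25,negative
11,25,163,positive,0.21,negative
12,12,82,positive,0.16,negative
13,7,193,positive,0.19,negative
14,3,172,positive,0.17,negative
15,14,123,positive,0.19,positive
16,2,74,positive,0.18,positive
17,7,212,positive,0.19,positive
18,7,72,positive,0.15,positive
19,9,102,positive,0.19,positive
20,12,105,positive,0.17,positive
21,23,45,negative,0.17,positive
22,8,99,positive,0.23,positive
23,18,45,negative,0.16,positive
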