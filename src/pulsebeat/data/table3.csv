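volunteer_id,actual_bpm,predicted_bpm
1,72,72
2,92,92
3,95,95
4,78,78
5,102,101
6,69,69
7,82,81
8,76,76
9,62,62
10,67,67
11,89,89
12,96,95
13,74,73
14,84,84
15,71,71
16,64,62
17,83,82
18,93,93
19,81,81
20,78,78
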