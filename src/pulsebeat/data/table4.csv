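volunteer_id,actual_bpm,predicted_bpm
1,72,72
2,92,92
3,95,94
4,78,78
5,102,102
6,69,69
7,82,82
8,76,76
9,62,60
10,67,67
11,89,89
12,96,96
13,74,74
14,84,84
15,71,71
16,64,64
17,83,83
18,93,93
19,81,81
20,78,78
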