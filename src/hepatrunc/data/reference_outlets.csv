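outlet_id,diameter_mm,flow_fraction_pct
1,3.58,4.07
2,3.23,0.79
3,4.94,4.37
4,4.12,3.45
5,3.39,2.99
6,3.31,0.69
7,3.05,0.62
8,3.08,0.62
9,3.35,0.62
10,3.33,0.62
11,3.60,0.34
12,3.22,0.11
13,3.36,0.11
14,3.26,0.11
15,3.10,1.24
16,2.77,1.24
17,3.25,3.66
18,3.20,1.80
19,3.35,0.33
20,4.08,3.05
21,3.26,0.84
22,3.26,0.23
23,2.29,0.11
24,3.34,0.12
25,3.11,0.50
26,3.48,0.22
27,3.01,0.22
28,3.32,3.63
29,3.40,2.60
30,2.76,1.33
31,3.01,0.26
32,3.02,0.07
33,2.74,0.77
34,2.94,0.07
35,3.35,0.97
36,4.41,8.94
37,3.73,0.82
38,2.85,0.82
39,3.33,13.32
40,2.75,6.03
41,3.25,3.39
42,3.08,2.99
43,2.92,6.00
44,3.69,2.59
45,3.55,3.95
46,3.01,4.32
47,3.81,0.59
48,2.54,3.47
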