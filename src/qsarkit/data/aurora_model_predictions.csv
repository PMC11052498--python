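ordinal,pic50_exp,hqsar,comfa,comsia,topomer
1,5.37,5.14,5.54,5.32,5.23
2,6.24,5.81,5.87,5.98,6.07
3,6.31,5.83,5.87,6.12,6.03
4,6.13,6.02,6.27,6.31,6.02
5,5.16,5.45,5.56,5.35,5.55
6,4.70,5.05,5.15,5.24,4.86
7,4.75,4.77,4.64,4.74,4.74
8,5.05,4.98,4.92,5.03,4.98
9,6.60,6.42,6.18,6.43,6.55
10,5.16,5.34,5.72,5.41,5.39
11,5.62,5.92,5.85,5.78,5.68
12,5.00,5.14,4.97,4.98,4.82
13,5.18,4.96,5.18,5.11,5.44
14,4.80,4.96,5.02,4.82,4.80
15,4.54,4.89,4.60,4.53,4.53
16,5.34,5.58,5.47,5.40,5.49
17,5.36,5.37,5.32,5.29,5.41
18,6.06,6.66,6.54,6.52,6.53
19,7.38,7.43,7.27,7.28,7.40
20,7.26,7.49,7.30,7.45,7.36
21,7.30,7.54,7.31,7.26,7.61
22,7.28,6.82,6.89,6.26,6.96
23,6.29,6.52,6.28,6.30,6.46
24,7.80,7.76,7.82,7.81,7.71
25,7.09,7.24,6.98,7.12,6.96
26,7.28,7.25,7.27,7.16,7.61
27,8.52,8.04,8.55,8.49,8.25
28,6.44,6.64,6.58,6.43,6.60
29,6.94,6.69,6.83,6.94,6.74
30,6.93,7.30,7.01,7.41,7.21
31,7.13,7.41,7.09,7.16,7.22
32,6.56,6.92,6.45,6.55,6.47
33,6.75,6.92,6.76,6.77,6.61
34,6.59,6.75,6.84,6.84,6.80
35,6.68,6.45,6.76,6.72,6.72
36,7.07,6.93,6.97,7.04,6.90
37,7.10,6.61,7.14,7.10,7.30
38,7.26,7.61,7.72,7.81,7.41
39,8.05,7.00,8.03,7.98,7.87
40,8.10,8.04,8.13,8.14,7.88
41,7.40,7.53,7.53,7.39,7.50
42,6.19,7.16,7.13,7.33,7.08
43,7.77,7.54,7.74,7.78,7.75
44,7.09,7.32,7.16,7.08,7.47
45,7.50,7.09,7.60,7.48,7.13
46,8.40,7.27,7.45,7.59,7.29
47,7.68,7.37,7.70,7.64,7.65
48,7.82,7.43,7.72,7.79,7.61
49,8.30,8.49,8.41,8.24,8.51
50,8.22,8.82,8.50,8.38,8.52
51,7.92,8.31,7.94,7.91,8.14
52,8.70,8.32,8.64,8.74,8.40
53,7.52,7.88,7.63,7.49,7.77
54,8.22,8.32,7.83,8.23,7.94
55,8.00,8.05,8.04,8.02,7.99
56,7.85,7.98,7.89,7.87,7.89
57,8.00,7.90,7.87,7.99,7.71
58,7.26,7.62,7.77,7.62,7.74
59,7.52,7.72,7.60,7.57,7.55
60,7.54,7.66,7.58,7.44,7.59
61,8.00,8.05,8.02,8.02,7.99
62,7.82,8.08,8.04,8.15,7.98
63,8.00,8.02,8.03,8.02,8.02
64,8.52,8.27,8.14,8.39,8.37
65,8.00,8.21,8.12,8.23,8.41
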