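ordinal,r1,r2,pic50,role
1,H,H,5.37,train
2,Cl,H,6.24,test
3,Br,H,6.31,train
4,CF3,H,6.13,train
5,Me,H,5.16,train
6,4-Methoxy-phenyl,H,4.70,test
7,Benzo[1.3]dioxole-5-yl,H,4.75,train
8,3-Hydroxy-phenyl,H,5.05,train
9,Cl,Cl,6.60,train
10,H,Me,5.16,test
11,H,Cl,5.62,train
12,H,m-Dimethylamino,5.00,train
13,H,p-Methoxy,5.18,train
14,H,m-Methoxy,4.80,test
15,H,o-Methoxy,4.54,train
16,H,p-Pyrrolidin-1-yl,5.34,train
17,H,p-Pyrid-2-yl,5.36,train
18,H,4-Dimethylamino-phenyl,6.06,test
19,Cl,4-Dimethylamino-phenyl,7.38,train
20,Br,4-Dimethylamino-phenyl,7.26,train
21,CN,4-Dimethylamino-phenyl,7.30,train
22,Cyclopropyl,4-Methoxy-phenyl,7.28,test
23,Br,H,6.29,train
24,Br,4-Dimethylaminomethyl-phenyl,7.80,train
25,Br,Ph,7.09,train
26,Cl,4-Methoxy-phenyl,7.28,test
27,Cl,4-Morpholin-4-ylmethyl-phenyl,8.52,train
28,Br,H,6.44,train
29,Cl,Phenylcarbamoylmethyl,6.94,train
30,Br,Pyridin-3-ylcarbamoylmethyl,6.93,test
31,Cl,(3-Chloro-phenylcarbamoyl)-methyl,7.13,train
32,Br,Phenylcarbamoyl,6.56,train
33,Br,Benzenesulfonyl,6.75,train
34,Br,Ph,6.59,test
35,Br,Isobutyl,6.68,train
36,Br,1-Pyridin-4-yl-ethyl,7.07,train
37,Cl,1-Phenyl-ethyl,7.10,train
38,Br,Pyridin-4-ylmethyl,7.26,test
39,Br,Pyridin-3-ylmethyl,8.05,train
40,Br,Pyrimidin-5-ylmethyl,8.10,train
41,Br,4-Chloro-benzyl,7.40,train
42,Br,Cyclopropylmethyl,6.19,test
43,Br,5-Methyl-isoxazol-3-ylmethyl,7.77,train
44,Br,2-Ethyl-oxazol-4-ylmethyl,7.09,train
45,Br,1-Methyl-4H-imidazol-2-ylmethyl,7.50,train
46,Br,Thiazol-4-ylmethyl,8.40,test
47,Cl,Pyridin-4-ylmethyl,7.68,train
48,Br,Pyridin-4-ylmethyl,7.82,train
49,Br,Pyridin-3-ylmethyl,8.30,train
50,Br,Pyrimidin-5-ylmethyl,8.22,test
51,Br,4-Chloro-benzyl,7.92,train
52,Br,5-Methyl-isoxazol-3-ylmethyl,8.70,train
53,Br,1-Methyl-4H-imidazol-2-ylmethyl,7.52,train
54,Br,Thiazol-4-ylmethyl,8.22,test
55,Br,Piperazin-1-ylmethyl,8.00,train
56,Br,Dimethylaminomethyl,7.85,train
57,Br,Aminomethyl,8.00,train
58,Cl,Aminomethyl,7.26,test
59,Br,2-Hydroxy-ethoxy,7.52,train
60,Cl,2-Hydroxy-ethoxy,7.54,train
61,Br,Piperazin-1-yl,8.00,train
62,Br,4-Methyl-piperazin-1-yl,7.82,test
63,Cl,4-Methyl-piperazin-1-yl,8.00,train
64,Br,Pyrazol-1-ylmethyl,8.52,train
65,Cl,Pyrazol-1-ylmethyl,8.00,train
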