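index,region,master_column
1,I,5
2,I,6
3,I,7
4,g.l,8
5,g.l,9
6,g.l,10
7,g.l,11
8,g.l,12
9,g.l,13
10,II,14
11,II,15
12,II,16
13,II,17
14,III,22
15,III,23
16,III,24
17,III,25
18,III,26
19,III,27
20,aC,33
21,aC,34
22,aC,35
23,aC,36
24,aC,37
25,aC,38
26,aC,39
27,aC,40
28,aC,41
29,aC,42
30,aC,43
31,b.l,44
32,b.l,45
33,b.l,46
34,b.l,47
35,b.l,48
36,b.l,49
37,b.l,50
38,IV,51
39,IV,52
40,IV,53
41,IV,54
42,V,61
43,V,62
44,V,63
45,GK,64
46,hinge,65
47,hinge,66
48,hinge,67
49,linker,68
50,linker,69
51,linker,70
52,linker,71
53,aD,72
54,aD,73
55,aD,74
56,aD,75
57,aD,76
58,aD,77
59,aD,78
60,aE,87
61,aE,88
62,aE,89
63,aE,90
64,aE,91
65,VI,95
66,VI,96
67,VI,97
68,c.l,98
69,c.l,99
70,c.l,100
71,c.l,101
72,c.l,102
73,c.l,103
74,c.l,104
75,c.l,105
76,VII,106
77,VII,107
78,VII,108
79,VIII,111
80,xDFG,112
81,xDFG,113
82,xDFG,114
83,xDFG,115
84,a.l,116
85,a.l,117
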