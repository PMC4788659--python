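template_id,label,operator,lbp_r1_k3,lbp_r1_k4,lbp_r1_k5,lbp_r2_k3,lbp_r2_k4,lbp_r2_k5,lbp_r3_k3,lbp_r3_k4,lbp_r3_k5
1,cirrhotic,dlbp,182,98,50,271,189,127,264,191,136
2,cirrhotic,dlbp,153,85,47,235,175,132,218,153,111
3,cirrhotic,dlbp,112,74,49,279,202,146,293,213,155
4,cirrhotic,dlbp,40,29,21,148,112,92,186,152,122
5,cirrhotic,dlbp,208,123,68,189,114,70,165,94,57
6,cirrhotic,dlbp,176,90,48,189,109,62,124,58,26
7,cirrhotic,dlbp,222,155,110,304,227,171,346,272,217
8,cirrhotic,dlbp,154,94,51,233,161,112,232,163,117
9,cirrhotic,dlbp,176,107,68,248,184,137,223,155,106
10,cirrhotic,dlbp,189,100,56,270,185,127,255,172,114
11,cirrhotic,dlbp,212,136,89,255,173,114,270,189,132
12,cirrhotic,dlbp,117,77,49,236,177,130,228,164,119
13,cirrhotic,dlbp,33,17,10,104,68,44,136,98,71
14,cirrhotic,dlbp,121,90,68,237,186,148,245,195,159
15,cirrhotic,dlbp,78,51,36,183,131,95,189,136,98
16,cirrhotic,dlbp,71,42,27,159,106,77,162,111,79
17,cirrhotic,dlbp,90,57,34,165,117,82,159,105,71
18,cirrhotic,dlbp,73,38,18,150,85,51,163,98,57
19,cirrhotic,dlbp,80,56,40,184,137,105,217,161,125
20,cirrhotic,dlbp,113,80,55,232,182,139,292,245,200
21,cirrhotic,dlbp,102,60,35,260,183,133,231,170,127
22,cirrhotic,dlbp,155,96,56,295,211,138,285,204,142
23,cirrhotic,dlbp,156,100,65,310,224,159,263,187,137
24,cirrhotic,dlbp,129,76,47,251,170,118,255,172,122
25,cirrhotic,dlbp,104,70,45,221,163,118,276,216,170
26,cirrhotic,dlbp,132,79,49,259,187,139,243,180,135
27,cirrhotic,dlbp,118,76,49,270,209,161,292,229,178
28,cirrhotic,dlbp,89,54,32,180,123,85,198,146,110
29,cirrhotic,dlbp,141,97,62,293,231,179,294,223,175
30,cirrhotic,dlbp,95,71,54,199,146,111,229,171,132
31,cirrhotic,dlbp,130,98,74,215,171,137,300,255,222
32,cirrhotic,dlbp,103,67,39,224,163,119,252,190,142
33,cirrhotic,dlbp,146,95,63,306,228,169,301,223,167
34,cirrhotic,dlbp,102,70,49,217,165,125,244,192,154
35,cirrhotic,dlbp,151,115,89,297,239,188,290,232,184
36,cirrhotic,dlbp,98,59,30,234,174,131,258,197,157
37,cirrhotic,dlbp,94,57,31,237,170,120,274,200,145
38,cirrhotic,dlbp,117,76,49,242,177,131,241,177,136
39,cirrhotic,dlbp,149,93,57,290,209,149,290,218,165
40,cirrhotic,dlbp,94,65,44,205,160,129,226,176,145
41,cirrhotic,dlbp,100,51,20,211,133,85,267,184,121
42,cirrhotic,dlbp,102,80,64,240,199,169,270,227,195
43,cirrhotic,dlbp,81,51,28,201,138,96,232,154,107
44,cirrhotic,dlbp,105,68,45,193,137,105,186,127,87
45,normal,dlbp,119,55,28,209,127,78,177,100,54
46,normal,dlbp,51,24,12,114,68,47,129,79,53
47,normal,dlbp,33,15,5,79,43,25,81,44,28
48,normal,dlbp,58,22,8,119,63,36,117,62,32
49,normal,dlbp,58,28,13,116,68,37,139,92,65
50,normal,dlbp,37,16,8,107,54,29,127,75,39
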