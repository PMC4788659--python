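template_id,label,k3,k4,k5
1,cirrhotic,0,0,0
2,cirrhotic,8,2,0
3,cirrhotic,0,0,0
4,cirrhotic,65,46,35
5,cirrhotic,0,0,0
6,cirrhotic,0,0,0
7,cirrhotic,0,0,0
8,cirrhotic,0,0,0
9,cirrhotic,3,2,1
10,cirrhotic,12,10,8
11,cirrhotic,0,0,0
12,cirrhotic,0,0,0
13,cirrhotic,0,0,0
14,cirrhotic,0,0,0
15,cirrhotic,0,0,0
16,cirrhotic,0,0,0
17,cirrhotic,0,0,0
18,cirrhotic,0,0,0
19,cirrhotic,0,0,0
20,cirrhotic,0,0,0
21,cirrhotic,0,0,0
22,cirrhotic,0,0,0
23,cirrhotic,0,0,0
24,cirrhotic,0,0,0
25,cirrhotic,0,0,0
26,cirrhotic,0,0,0
27,cirrhotic,0,0,0
28,cirrhotic,0,0,0
29,cirrhotic,0,0,0
30,cirrhotic,0,0,0
31,cirrhotic,1,0,0
32,cirrhotic,0,0,0
33,cirrhotic,0,0,0
34,cirrhotic,0,0,0
35,cirrhotic,0,0,0
36,cirrhotic,0,0,0
37,cirrhotic,0,0,0
38,cirrhotic,0,0,0
39,cirrhotic,0,0,0
40,cirrhotic,24,21,19
41,cirrhotic,0,0,0
42,cirrhotic,13,10,7
43,cirrhotic,0,0,0
44,cirrhotic,0,0,0
45,normal,0,0,0
46,normal,0,0,0
47,normal,0,0,0
48,normal,0,0,0
49,normal,0,0,0
50,normal,0,0,0
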