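template_id,label,operator,lbp_r1_k3,lbp_r1_k4,lbp_r1_k5,lbp_r2_k3,lbp_r2_k4,lbp_r2_k5,lbp_r3_k3,lbp_r3_k4,lbp_r3_k5
1,cirrhotic,lbp,719,554,419,669,536,426,582,464,363
2,cirrhotic,lbp,624,451,334,556,416,317,520,382,288
3,cirrhotic,lbp,709,542,409,585,451,349,589,469,381
4,cirrhotic,lbp,597,471,369,593,486,396,575,473,393
5,cirrhotic,lbp,597,428,307,572,414,295,491,343,237
6,cirrhotic,lbp,551,387,275,500,357,263,423,267,167
7,cirrhotic,lbp,798,641,515,761,628,518,737,622,526
8,cirrhotic,lbp,713,558,436,682,551,443,626,509,414
9,cirrhotic,lbp,724,566,449,660,520,405,635,499,403
10,cirrhotic,lbp,684,499,369,689,526,409,512,368,271
11,cirrhotic,lbp,594,438,325,567,430,319,536,411,317
12,cirrhotic,lbp,795,659,553,743,618,508,714,589,480
13,cirrhotic,lbp,611,456,345,468,348,252,529,410,323
14,cirrhotic,lbp,757,609,496,796,668,566,768,661,574
15,cirrhotic,lbp,707,555,434,681,559,454,617,511,423
16,cirrhotic,lbp,572,411,304,636,488,382,587,459,359
17,cirrhotic,lbp,582,431,319,581,435,332,582,466,379
18,cirrhotic,lbp,536,358,241,554,401,292,556,407,299
19,cirrhotic,lbp,622,457,337,637,507,401,617,506,414
20,cirrhotic,lbp,814,697,591,746,643,553,709,621,542
21,cirrhotic,lbp,717,564,447,716,582,474,663,542,450
22,cirrhotic,lbp,723,570,439,729,593,478,723,597,484
23,cirrhotic,lbp,813,657,529,783,644,527,726,601,497
24,cirrhotic,lbp,666,498,375,637,482,363,619,482,378
25,cirrhotic,lbp,630,506,405,622,510,419,569,471,388
26,cirrhotic,lbp,652,495,378,619,470,369,607,476,386
27,cirrhotic,lbp,643,486,362,649,517,416,582,475,388
28,cirrhotic,lbp,610,475,369,620,480,376,554,437,347
29,cirrhotic,lbp,747,612,497,719,598,496,696,581,480
30,cirrhotic,lbp,618,469,358,653,528,424,618,507,423
31,cirrhotic,lbp,799,680,587,756,658,570,695,611,537
32,cirrhotic,lbp,579,421,298,583,440,327,589,462,355
33,cirrhotic,lbp,792,635,506,753,609,488,719,596,498
34,cirrhotic,lbp,674,527,414,670,531,421,657,533,437
35,cirrhotic,lbp,715,582,473,728,603,509,596,502,423
36,cirrhotic,lbp,774,635,517,751,623,515,715,594,495
37,cirrhotic,lbp,748,596,464,765,635,527,731,627,531
38,cirrhotic,lbp,514,367,269,513,377,288,518,404,324
39,cirrhotic,lbp,728,582,456,736,611,506,705,577,474
40,cirrhotic,lbp,608,477,375,630,512,416,569,470,388
41,cirrhotic,lbp,637,474,347,638,485,358,639,501,390
42,cirrhotic,lbp,737,609,510,732,617,526,706,612,529
43,cirrhotic,lbp,708,549,423,675,529,405,642,517,412
44,cirrhotic,lbp,544,407,303,511,378,276,506,386,295
45,normal,lbp,517,343,237,444,297,210,415,279,187
46,normal,lbp,648,464,333,680,516,391,670,531,423
47,normal,lbp,605,428,300,616,444,332,654,511,410
48,normal,lbp,582,391,264,477,318,218,418,282,198
49,normal,lbp,658,472,333,712,541,427,734,592,482
50,normal,lbp,590,391,261,622,450,324,647,489,372
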