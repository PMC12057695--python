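trial_id,deprivation_days,n_slugs,n_anemones,max_group_size,mean_group_size,n_not_feeding
1,7,8,8,2,1,7
2,7,8,8,4,2,2
3,7,8,8,4,2.5,3
4,7,8,8,1,1.4,1
5,7,8,8,4,1.75,1
6,7,8,8,3,1.6,0
7,7,8,8,6,3.5,1
8,7,8,8,1,1,6
9,7,8,8,3,2.33,1
10,7,8,8,3,1.75,1
11,7,8,8,3,2,2
12,7,8,8,3,1.33,3
13,7,8,8,3,1.75,1
14,7,8,8,3,1.75,1
15,7,8,8,2,1.67,3
16,3,8,8,4,2,0
17,3,8,8,3,2,2
18,3,8,8,5,2.33,1
19,3,8,8,2,1.5,2
20,3,8,8,3,1.67,3
21,3,8,8,6,4,0
22,3,8,8,3,2,0
23,3,8,8,3,2,0
24,3,8,8,2,1.33,0
25,3,8,8,2,1,4
26,3,8,8,2,1.4,1
27,3,8,8,2,1.5,2
28,3,8,8,2,1.33,0
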