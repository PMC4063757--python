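subject,Y,fusiform_caudal,angular,superior_parietal,lingual,pericalcarine,lateral_occipital,cuneus
1,1,0,1,1,1,1,1,1
2,1,1,1,1,1,1,1,1
3,1,0,1,1,1,1,1,1
4,1,1*,1,1,1,1,1,1*
5,1,1,0,1,1,1,1,0
6,1,1,1,1,1,1,1,1
7,1,1*,1,1,1,1,1,1
8,1,0,1,1,1,1,1,1
9,1,1,1,1,1,1,1,1
10,1,0,1,1,1,1,1,0
11,1,0,1,1,1,1,1,1
12,1,0,1,1,1,1,1,1
13,1,1,1,1,1,1,1,0
14,1,1,1,1,1,1,1,0
15,1,0,1,1,1,1,1,0
16,1,1*,1,1,1,1,1,1
17,1,0,1,1,1,1,1,1
18,1,1*,1,1,1,1,1,0
19,1,1,1,1,1,1,1,0
20,1,0,1,1,1,1,1,0
% of 1,100.00%,55.00%,95.00%,100.00%,100.00%,100.00%,100.00%,60.00%
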