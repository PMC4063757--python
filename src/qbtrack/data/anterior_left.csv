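subject,Y,caudal_middle_frontal,lateral_orbitofrontal,medial_orbitofrontal,paracentral,pars_opercularis,pars_orbitalis,pars_triangularis,precentral,rostral_middle_frontal,superior_frontal,frontal_pole
1,1,0,0,0,0,1,1,1,0,1,1,1
2,1,0,1,1,0,1,1,1,0,1,1,1
3,1,1,0,0,0,1,1,1,0,1,1,1
4,1,0,1,1,0,0,1,1,0,1,1,1
5,1,0,1,1*,0,1,1,1,0,1,0,0
6,1,0,1,1,0,1*,1,1,0,1,1,1
7,1,0,1,1*,0,1,1,1,0,1,1,1*
8,1,0,1,1*,0,1,1,1,0,1,1,1
9,1,0,0,0,0,1,1,1,0,1,1,1*
10,1,1*,1,1,0,1*,1,1,0,1,1,1
11,1,0,1,1*,0,1,1,1,0,1,1,1
12,1,0,1,1,0,0,1,1,0,1,1,1
13,1,0,1,0,0,1,1,1,0,1,1,1*
14,1,0,1,1,0,0,1,1,0,1,1,1
15,1,0,1,1,0,1*,1,1,0,1,1,1*
16,1,0,1,0,0,1*,1,1,0,1,1,1
17,1,0,1,1,0,0,1,1,0,1,1,1
18,1,0,1,1,0,0,1,1,0,1,1,1
19,1,0,1,1,0,1,1,1,0,1,1,1
20,1,0,1,1,0,1,1,1,0,1,1,1*
% of 1,100.00%,10.00%,85.00%,75.00%,0.00%,75.00%,100.00%,100.00%,0.00%,100.00%,95.00%,95.00%
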