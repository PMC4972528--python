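case,age_months,n_samples,group
1,10,2,heterogeneous
2,18,3,homogeneous
3,32,3,homogeneous
4,58,3,heterogeneous
5,48,2,heterogeneous
6,19,3,homogeneous
7,10,3,heterogeneous
8,34,3,heterogeneous
9,32,3,heterogeneous
10,36,3,bilateral
11,20,3,heterogeneous
12,6,4,homogeneous
13,27,5,heterogeneous
14,12,2,heterogeneous
15,14,6,heterogeneous
16,28,3,bilateral
17,5,5,bilateral
18,50,3,heterogeneous
19,42,6,heterogeneous
20,29,5,bilateral
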