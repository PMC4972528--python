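tumor,n_samples,n_positive
11,3,3
15,6,6
19,6,6
4,3,1
9,3,1
16R,2,1
20R,3,2
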