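chrom	length	centromere
1	249250621	125000000
2	243199373	93300000
3	198022430	91000000
4	191154276	50400000
5	180915260	48400000
6	171115067	61000000
7	159138663	59900000
8	146364022	45600000
9	141213431	49000000
10	135534747	40200000
11	135006516	53700000
12	133851895	35800000
13	115169878	17900000
14	107349540	17600000
15	102531392	19000000
16	90354753	36600000
17	81195210	24000000
18	78077248	17200000
19	59128983	26500000
20	63025520	27500000
21	48129895	13200000
22	51304566	14700000
X	155270560	60600000
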