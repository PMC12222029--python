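chrom	p_start	p_end	q_start	q_end
1	1	121535434	124535435	249250621
2	1	92326171	95326172	243199373
3	1	90504854	93504855	198022430
4	1	49660117	52660118	191154276
5	1	46405641	49405642	180915260
6	1	58830166	61830167	171115067
7	1	58054331	61054332	159138663
8	1	43838887	46838888	146364022
9	1	47367679	50367680	141213431
10	1	39254935	42254936	135534747
11	1	51644205	54644206	135006516
12	1	34856694	37856695	133851895
13	1	16000000	19000001	115169878
14	1	16000000	19000001	107349540
15	1	17000000	20000001	102531392
16	1	35335801	38335802	90354753
17	1	22263006	25263007	81195210
18	1	15460898	18460899	78077248
19	1	24681782	27681783	59128983
20	1	26369569	29369570	63025520
21	1	11288129	14288130	48129895
22	1	13000000	16000001	51304566
X	1	58632012	61632013	155270560
Y	1	10104553	13104554	59373566
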