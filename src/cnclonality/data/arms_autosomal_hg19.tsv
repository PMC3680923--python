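chrom	arm	start	end
chr1	p	1	121535434
chr1	q	124535435	249250621
chr2	p	1	92326171
chr2	q	95326172	243199373
chr3	p	1	90504854
chr3	q	93504855	198022430
chr4	p	1	49660117
chr4	q	52660118	191154276
chr5	p	1	46405641
chr5	q	49405642	180915260
chr6	p	1	58830166
chr6	q	61830167	171115067
chr7	p	1	58054331
chr7	q	61054332	159138663
chr8	p	1	43838887
chr8	q	46838888	146364022
chr9	p	1	47367679
chr9	q	50367680	141213431
chr10	p	1	39254935
chr10	q	42254936	135534747
chr11	p	1	51644205
chr11	q	54644206	135006516
chr12	p	1	34856694
chr12	q	37856695	133851895
chr13	q	19000001	115169878
chr14	q	19000001	107349540
chr15	q	20000001	102531392
chr16	p	1	35335801
chr16	q	38335802	90354753
chr17	p	1	22263006
chr17	q	25263007	81195210
chr18	p	1	15460898
chr18	q	18460899	78077248
chr19	p	1	24681782
chr19	q	27681783	59128983
chr20	p	1	26369569
chr20	q	29369570	63025520
chr21	q	14288130	48129895
chr22	q	16000001	51304566
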