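sample	tcga_alias	gene_5p	gene_3p	tx_5p	tx_3p	junction_reads	wt5	wt3	band	chrom	strand_5p	strand_3p	pos_5p	pos_3p	type
SN214	TCGA-74-6583	MON2	MARS	NM_015026	NM_004990	47	6	3	12q14	chr12	+	+	62981936	57883990	In-frame fusion
SN214	TCGA-74-6583	MDM1	UAR	NM_020128	NA	196	4	NA	12q15	chr12	-	-	68717849	68876024	Extended 3' UTR
SN214	TCGA-74-6583	SLC35E3	UAR	NM_018656	NA	470	0	NA	12q15	chr12	+	-	69145972	68489752	Truncated gene
SN238	NA	YEATS4	SLC35E3	NM_006530	NM_018656	232	6	4	12q15	chr12	+	+	69753803	69152935	In-frame fusion
SN161	NA	PIK3C2B	DSTYK	NM_002646	NM_199462	95	3	0	1q32	chr1	-	-	204426856	205119924	In-frame fusion
SN195-1	NA	PLEKHA6	PIK3C2B	novel	NM_002646	23	0	13	1q32	chr1	-	-	204320007	204439018	5' UTR
SN161	NA	CREB1	PARD3B	NM_004379	NM_057177	65	10	1	2q33	chr2	+	+	208442379	205829875	Out-of-frame fusion
SN214	TCGA-74-6583	SCFD2	CLOCK	NM_152540	NM_004898	10	4	6	4q12	chr4	-	-	53786892	56301763	In-frame fusion
SN159	NA	SEC61G	UAR	ENST00000480303	NA	484	44	NA	7p11	chr7	+	-	51654097	54821716	No protein product
SN161	NA	LANCL2	RP11-745C15	NM_018697	ENST00000439413	274	8	0	7p11	chr7	+	+	55469013	54872359	Truncated gene
SN218	NA	ZNF713	UAR	uc003tra	NA	51	2	NA	7p11	chr7	+	+	55991300	56082944	Truncated gene
SN154	TCGA-74-6573	ZNF713	UAR	uc003tra	NA	14	10	NA	7p11	chr7	+	-	55980418	55945274	Truncated gene
SN187	TCGA-74-6578	FGFR3	TACC3	NM_000142	NM_006342	13	31	0	4p16	chr4	+	+	1808661	1737458	In-frame fusion
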