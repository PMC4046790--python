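sample	local_id	cohort	gene_5p	chrom_5p	pos_5p	gene_3p	chrom_3p	pos_3p
TCGA-06-5856-01A	NA	tcga	TSFM	chr12	58180073	IFNG	chr12	68549194
TCGA-28-5207-01A	NA	tcga	TSFM	chr12	58191066	TJAP1	chr6	43473030
TCGA-19-2624-01A	NA	tcga	PPM1H	chr12	63182005	MDM2	chr12	69202987
TCGA-06-5856-01A	NA	tcga	C12orf49	chr12	117175594	MDM2	chr12	69229608
TCGA-27-1835-01A	NA	tcga	FGFR3	chr4	1808660	TACC3	chr4	1741428
TCGA-76-4925-01A	NA	tcga	FGFR3	chr4	1808660	TACC3	chr4	1739324
TCGA-74-6578	SN187	discovery	FGFR3	chr4	1808661	TACC3	chr4	1737458
TCGA-06-0129-01A	NA	tcga	FRS2	chr12	69864309	KIF5A	chr12	57957221
TCGA-41-2571-01A	NA	tcga	FRS2	chr12	69864309	DTX3	chr12	58002302
TCGA-06-0141-01A	NA	tcga	GIGYF2	chr2	233562102	ECEL1	chr2	233345866
TCGA-28-2499-01A	NA	tcga	GIGYF2	chr2	233613791	PPP1R7	chr2	242107151
TCGA-06-0187-01A	NA	tcga	HMGA2	chr12	66232348	NUP107	chr12	69109406
TCGA-06-0686-01A	NA	tcga	NUP107	chr12	69096563	RP11-123O10	chr12	67302585
TCGA-14-1034-02B	NA	tcga	ADAMTS17	chr15	100589061	LPAR1	chr9	113638001
TCGA-06-0129-01A	NA	tcga	NAA15	chr4	140222984	LPAR1	chr9	113638001
TCGA-06-0125-01A	NA	tcga	ARID1A	chr1	27094489	RNF31	chr14	24624365
TCGA-06-0125-02A	NA	tcga	ARID1A	chr1	27094489	RNF31	chr14	24624365
TCGA-28-2514-01A	NA	tcga	ARID1A	chr1	27024031	BEND5	chr1	49202124
TCGA-19-2619-01A	NA	tcga	BCAN	chr1	156628525	NTRK1	chr1	156844697
TCGA-06-5411-01A	NA	tcga	NFASC	chr1	204951147	NTRK1	chr1	156844362
TCGA-06-0157-01A	NA	tcga	NFASC	chr1	204797909	SOX13	chr1	204082042
TCGA-06-0210-01A	NA	tcga	NFASC	chr1	204797910	PRELP	chr1	203452296
TCGA-12-1597-01B	NA	tcga	NFASC	chr1	204951147	RTN3	chr11	63525627
TCGA-06-5418-01A	NA	tcga	CEP85L	chr6	118802941	ROS1	chr6	117641192
TCGA-14-2554-01A	NA	tcga	CEP85L	chr6	118953615	SYTL3	chr6	159166511
TCGA-06-2559-01A	NA	tcga	CTDSP2	chr12	58240154	LOC100422737	chr6	107172534
TCGA-41-2571-01A	NA	tcga	CTDSP2	chr12	58240154	C12orf10	chr12	53699691
TCGA-19-2624-01A	NA	tcga	EGFR	chr7	55087057	PPM1H	chr12	63195939
TCGA-28-5209-01A	NA	tcga	EGFR	chr7	55268105	PSPHP1	chr7	55840873
TCGA-27-1837-01A	NA	tcga	EGFR	chr7	55268106	SEPT14	chr7	55863785
TCGA-28-2513-01A	NA	tcga	EGFR	chr7	55268106	SEPT14	chr7	55863785
TCGA-32-5222-01A	NA	tcga	EGFR	chr7	55268106	SEPT14	chr7	55863785
TCGA-12-5299-01A	NA	tcga	EGFR	chr7	55087057	RP11-436F9	chr7	54414986
TCGA-06-0219-01A	NA	tcga	EGFR	chr7	55240816	RP11-745C15.2	chr7	54860605
TCGA-12-3653-01A	NA	tcga	EGFR	chr7	55269474	RP11-745C15.2	chr7	54850284
TCGA-12-3652-01A	NA	tcga	VOPP1	chr7	55639963	RP11-745C15.2	chr7	54850800
TCGA-32-2638-01A	NA	tcga	LANCL2	chr7	55433921	RP11-745C15.2	chr7	54850800
SN161	SN161	discovery	LANCL2	chr7	55469013	RP11-745C15.2	chr7	54872357
TCGA-06-0211-01A	NA	tcga	LANCL2	chr7	55433921	GS1-18A18	chr7	54643985
TCGA-06-0211-01B	NA	tcga	LANCL2	chr7	55433921	GS1-18A18	chr7	54643985
TCGA-06-0211-01A	NA	tcga	LANCL2	chr7	55479782	SEPT14	chr7	55886916
TCGA-06-0211-01B	NA	tcga	LANCL2	chr7	55479782	SEPT14	chr7	55886916
TCGA-28-2513-01A	NA	tcga	LANCL2	chr7	55433922	SEPT14	chr7	55914330
TCGA-14-0817-01A	NA	tcga	LANCL2	chr7	55469012	PSPH	chr7	56082822
TCGA-28-5209-01A	NA	tcga	LANCL2	chr7	55433921	RP11-310H4	chr7	55714590
TCGA-14-1829-01A	NA	tcga	SEC61G	chr7	54823471	RP11-310H4	chr7	55727802
TCGA-06-0211-02A	NA	tcga	SEC61G	chr7	54825187	EGFR	chr7	55224225
SN159	SN159	discovery	SEC61G	chr7	51654097	UAR	chr7	54821716
TCGA-06-0211-01B	NA	tcga	MRPS17	chr7	56019622	RP11-436F9	chr7	54411333
TCGA-06-5856-01A	NA	tcga	XRCC6BP1	chr12	58335421	SRRM4	chr12	119583185
TCGA-06-0138-01A	NA	tcga	YEATS4	chr12	69764754	XRCC6BP1	chr12	58339410
TCGA-26-5135-01A	NA	tcga	SLC16A7	chr12	59990016	RP11-362K2.2	chr12	59206195
TCGA-02-2485-01A	NA	tcga	MARS	chr12	57898081	RP11-362K2.2	chr12	59195041
TCGA-74-6583	SN214	discovery	MON2	chr12	62981936	MARS	chr12	57883989
TCGA-74-6583	SN214	discovery	SLC35E3	chr12	69145972	UAR	chr12	68489752
SN238	SN238	discovery	YEATS4	chr12	69753803	SLC35E3	chr12	69152935
SN161	SN161	discovery	PIK3C2B	chr1	204426856	DSTYK	chr1	205119924
SN195-1	SN195-1	discovery	PLEKHA6	chr1	204320007	PIK3C2B	chr1	204439018
SN218	SN218	discovery	ZNF713	chr7	55991300	UAR	chr7	56082944
TCGA-74-6573	SN154	discovery	ZNF713	chr7	55980418	UAR	chr7	55945274
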