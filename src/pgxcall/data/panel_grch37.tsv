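# 67-locus pharmacogene panel; coordinates are 1-based GRCh37 (hg19).
# aliases: semicolon-joined rsid synonyms ("." if none); label: descriptive name ("." if none).
rsid	aliases	gene	chrom	pos	ref	alt	region_class	label
rs1801131	.	MTHFR	1	11854476	T	G	exonic	.
rs1801133	.	MTHFR	1	11856378	G	A	exonic	.
rs67376798	.	DPYD	1	97547947	T	A	exonic	c.2846A>T
rs3918290	.	DPYD	1	97915614	C	T	intronic	IVS14+1G>A
rs12248560	.	CYP2C19	10	96521657	C	T	upstream	CYP2C19*17
rs28399504	.	CYP2C19	10	96522463	A	G	exonic	CYP2C19*4
rs41291556	.	CYP2C19	10	96535173	T	C	exonic	CYP2C19*8
rs17884712	.	CYP2C19	10	96535210	G	A	exonic	CYP2C19*9
rs4986893	.	CYP2C19	10	96540410	G	A	exonic	CYP2C19*3
rs4244285	.	CYP2C19	10	96541616	G	A	exonic	CYP2C19*2
rs1799853	.	CYP2C9	10	96702047	C	T	exonic	CYP2C9*2
rs9332131	.	CYP2C9	10	96731043	TA	T	exonic	CYP2C9*6
rs28371686	.	CYP2C9	10	96740981	C	G	exonic	CYP2C9*5
rs1057910	.	CYP2C9	10	96741053	A	C	exonic	CYP2C9*3
rs1800497	.	ANKK1	11	113270828	G	A	exonic	Taq1A
rs1954787	.	GRIK4	11	120533313	T	C	intronic	.
rs2306283	.	SLCO1B1	12	21329738	A	G	exonic	.
rs4149056	.	SLCO1B1	12	21331549	T	C	exonic	SLCO1B1*5
rs9923231	.	VKORC1	16	31107689	C	T	upstream	-1639G>A
rs2108622	.	CYP4F2	19	15990431	C	T	exonic	V433M
rs12979860	.	IFNL3	19	39738787	C	T	upstream	.
rs1051266	.	SLC19A1	21	46957794	C	T	exonic	.
rs4633	.	COMT	22	19950235	C	T	exonic	.
rs4818	.	COMT	22	19951207	C	G	exonic	.
rs4680	.	COMT	22	19951271	G	A	exonic	V158M
rs2228001	.	TMEM	3	14187449	A	C	exonic	.
rs2231142	.	ABCG2	4	89052323	G	T	exonic	Q141K
rs2231137	.	ABCG2	4	89061114	C	T	exonic	V12M
rs1142345	.	TPMT	6	18130918	T	C	exonic	TPMT*3C
rs1800584	.	TPMT	6	18130687	C	T	intronic	TPMT*4
rs1800460	.	TPMT	6	18139228	C	T	exonic	TPMT*3B
rs1800462	.	TPMT	6	18143955	C	G	exonic	TPMT*2
rs1061235	.	HLA	6	29912386	A	T	exonic	HLA-A*31:01 tag
rs2395029	.	HLA	6	31431780	T	G	exonic	HLA-B*57:01 tag
rs1128503	.	ABCB1	7	87179601	G	A	exonic	1236C>T
rs2032582	.	ABCB1	7	87160618	C	A	exonic	2677G>T
rs1045642	.	ABCB1	7	87138645	G	A	exonic	3435C>T
rs776746	.	CYP3A5	7	99270539	T	C	intronic	CYP3A5*3
rs1080985	.	CYP2D6	22	42528382	G	C	upstream	-1584C>G
rs28735595	.	CYP2D6	22	42528101	C	T	upstream	.
rs769258	.	CYP2D6	22	42526763	C	T	exonic	31G>A
rs1065852	.	CYP2D6	22	42526694	G	A	exonic	100C>T
rs5030862	.	CYP2D6	22	42526670	C	T	exonic	.
rs5030863	rs201377835	CYP2D6	22	42526656	C	G	exonic	.
rs72549357	rs774671100	CYP2D6	22	42526635	C	CT	exonic	.
rs61736512	.	CYP2D6	22	42525820	C	T	exonic	1659G>A
rs28371706	.	CYP2D6	22	42525772	C	T	exonic	1023C>T
rs1058164	.	CYP2D6	22	42525131	C	G	exonic	1661G>C
rs5030655	.	CYP2D6	22	42525086	AG	A	exonic	1707delT
rs5030865	.	CYP2D6	22	42525035	C	A	exonic	1758G>T
rs3892097	.	CYP2D6	22	42524947	C	T	intronic	1846G>A
rs72549356	rs553846709	CYP2D6	22	42524890	G	A	exonic	.
rs72549354	.	CYP2D6	22	42524856	C	T	exonic	.
rs72549353	rs758320086	CYP2D6	22	42524820	G	A	exonic	.
rs35742686	.	CYP2D6	22	42524244	GT	G	exonic	2549delA
rs72549352	.	CYP2D6	22	42524210	A	G	exonic	.
rs72549351	.	CYP2D6	22	42524200	C	T	exonic	.
rs5030656	.	CYP2D6	22	42524176	CAAG	C	exonic	2615_2617delAAG
rs16947	.	CYP2D6	22	42523943	C	T	exonic	2850C>T
rs5030867	.	CYP2D6	22	42523858	T	G	exonic	2935A>C
rs72549349	.	CYP2D6	22	42523805	A	C	exonic	.
rs2837172	.	CYP2D6	22	42523700	A	G	intronic	.
rs72549347	rs147960066	CYP2D6	22	42523650	G	A	intronic	.
rs72549346	.	CYP2D6	22	42523610	C	T	intronic	.
rs28371731	rs4987144	CYP2D6	22	42523540	G	A	intronic	.
rs765776661	.	CYP2D6	22	42522964	GACT	G	exonic	G4125_4133 T
rs1135840	.	CYP2D6	22	42522613	C	G	exonic	4180G>C
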