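# Star-allele definitions over the bundled panel, pre-collapsed to the resolution
# the panel's tag variants can discriminate (sub-alleles sharing tags fold into the
# parent star). One row per (star, defining variant); the reference star (*1) and
# the CYP2D6 whole-gene deletion (*5) carry rsid "." and required_allele ".".
# activity_value: CYP2D6 activity-score contribution per copy ("NA" for genes
# phenotyped by allele function class). function: normal|decreased|no_function|increased.
gene	star_name	rsid	required_allele	activity_value	function
CYP2D6	*1	.	.	1.0	normal
CYP2D6	*2	rs16947	T	1.0	normal
CYP2D6	*35	rs769258	T	1.0	normal
CYP2D6	*9	rs5030656	C	0.5	decreased
CYP2D6	*10	rs1065852	A	0.5	decreased
CYP2D6	*17	rs28371706	T	0.5	decreased
CYP2D6	*29	rs61736512	T	0.5	decreased
CYP2D6	*3	rs35742686	G	0.0	no_function
CYP2D6	*4	rs3892097	T	0.0	no_function
CYP2D6	*5	.	.	0.0	no_function
CYP2D6	*6	rs5030655	A	0.0	no_function
CYP2D6	*7	rs5030867	G	0.0	no_function
CYP2D6	*8	rs5030865	A	0.0	no_function
CYP2C19	*1	.	.	NA	normal
CYP2C19	*2	rs4244285	A	NA	no_function
CYP2C19	*3	rs4986893	A	NA	no_function
CYP2C19	*4	rs28399504	G	NA	no_function
CYP2C19	*8	rs41291556	C	NA	no_function
CYP2C19	*9	rs17884712	A	NA	decreased
CYP2C19	*17	rs12248560	T	NA	increased
CYP2C9	*1	.	.	NA	normal
CYP2C9	*2	rs1799853	T	NA	decreased
CYP2C9	*3	rs1057910	C	NA	no_function
CYP2C9	*5	rs28371686	G	NA	decreased
CYP2C9	*6	rs9332131	T	NA	no_function
CYP3A5	*1	.	.	NA	normal
CYP3A5	*3	rs776746	C	NA	no_function
TPMT	*1	.	.	NA	normal
TPMT	*2	rs1800462	G	NA	no_function
TPMT	*3A	rs1800460	T	NA	no_function
TPMT	*3A	rs1142345	C	NA	no_function
TPMT	*3B	rs1800460	T	NA	no_function
TPMT	*3C	rs1142345	C	NA	no_function
TPMT	*4	rs1800584	T	NA	no_function
DPYD	*1	.	.	NA	normal
DPYD	*2A	rs3918290	T	NA	no_function
DPYD	c.2846A>T	rs67376798	A	NA	decreased
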