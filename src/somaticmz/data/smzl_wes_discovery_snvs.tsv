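gene	case	chrom	position	exon	coverage_tumor	snv_frequency	quality_score	nucleotide_change	aa_change	footnote	sift_prediction	polyphen2_prediction
CEBPZ	1	2	37456150	2	21	0.38	27.0	c.186 T > A	p.D62E		Tolerated	Benign
MYD88	1	3	38182641	5	49	0.49	30.0	c.794 T > C	p.L265P		Damaging	Probably damaging
TTC14	1	3	180320802	2	21	0.24	32.0	c.285A > G	p.E95E	splice site	Tolerated	Benign
SLC6A7	1	5	149574417	2	33	0.27	23.0	c.160 T > C	p.C54R		Damaging	Probably damaging
BTN2A2	1	6	26384057	2	29	0.24	32.0	c.8C > T	p.P3L		Damaging	Possibly damaging
POM121	1	7	72396892	5	41	0.29	20.0	c.737C > T	p.P246L		Damaging	Probably damaging
MUC12	1	7	100645822	2	32	0.25	31.0	c.12407C > A	p.P4136H		Tolerated	Probably damaging
STMN4	1	8	27098767	5	40	0.25	30.0	c.203A > C	p.D68A		Damaging	Benign
KRTAP5-2	1	11	1619441	1	20	0.35	27.0	c.40 T > C	p.C14R		N/A	Possibly damaging
CACNA1C	1	12	2794937	47	63	0.25	20.0	c.5823C > T	p.T1941M		Tolerated	N/A
LOC728888	1	16	29395118		61	0.15	18.0	c.1135G > T	p.G379W		Damaging	Probably damaging
CDC27	1	17	45247333	4	42	0.26	28.0	c.327G > T	p.E109D		Tolerated	Benign
FBXO44	2	1	11718850	4	21	0.19	20.28	c.421G > A	p.V141I		Tolerated	Benign
NOTCH2	2	1	120458255	34	65	0.48	22.0	c.7090C > T	p.Q2364	stop gained	Stop gained	N/A
SMYD1	2	2	88396251	6	26	0.50	26.0	c.836G > T	p.C279F		Damaging	Probably damaging
ZNF608	2	5	123982418	4	73	0.33	26.0	c.3659A > G	p.D1220G		Damaging	Probably damaging
ZNF451	2	6	57013380	10	30	0.20	24.93	c.2497 T > C	p.F833L		Tolerated	Benign
PDE10A	2	6	165829696	13	116	0.37	22.0	c.1072G > A	p.A358T		Tolerated	Probably damaging
PCLO	2	7	82784519	2	57	0.18	17.0	c.1438C > T	p.P480S		Tolerated	Benign
PRSS1	2	7	142460369	4	26	0.23	19.0	c.542G > A	p.S181N		Tolerated	Benign
CSMD1	2	8	2800055	69	74	0.36	24.0	c.8683A > T	p.I2895F		Damaging	N/A
APOA4	2	11	116692500	3	20	0.35	31.0	c.274G > A	p.A92T		Tolerated	Benign
HERC2	2	15	28458971	42	23	0.22	25.97	c.6703C > A	p.R2235S		Tolerated	Possibly damaging
CDC27	2	17	45229185	9	90	0.23	29.0	c.1075G > C	p.G359R		Tolerated	Possibly damaging
GRIN2C	2	17	72842984	10	39	0.44	23.0	c.2077C > T	p.R693C		Damaging	Probably damaging
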