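# 52 positive-control cases: patients with Lynch-syndrome-related colorectal
# (CRC, subjects 1-29) or endometrial (EC, subjects 30-52) cancer and a known
# pathogenic germline MMR alteration, transcribed from published clinical
# report summaries. The pathogenic alteration is assessed as if it were the
# queried VUS. braf_methylation holds "BRAF, methylation" for CRC rows and the
# methylation result alone for EC rows, verbatim. somatic_inactivating flags
# are the reporting laboratory's assertions, one per semicolon-separated
# somatic event. printed_code is provenance only (never consumed by logic);
# expected_class is POSITIVE iff the printed code is in families II-V.
# reported_organ preserves the source's (partly conflicting) organ labels.
subject_id	cancer_type	reported_organ	premm5	gene	cdna	protein	braf_methylation	msi	ihc	somatic	somatic_inactivating	printed_code	expected_class
1	CRC	Colorectal	5.70%	MLH1	c.116+2T>G		Neg, Unmethylated MLH1 promoter	MSI-High	Loss of MLH1 and PMS2	MLH1 single-copy loss	yes	II-III	POSITIVE
2	CRC	Colorectal	36.40%	MLH1	c.1783_1784delAG	p.S595Wfs*14	Neg, NA	MSI-High	Loss of MLH1 and PMS2	MLH1:c.790+5G>A	yes	II-I	POSITIVE
3	CRC	Endometrial and Colorectal	7.2%	MSH2	c.704_705del	p.K235Rfs*20	Neg, NA	MSI-High	Loss of MSH2 and MSH6	MSH2:c.2446C>T (p.Q816*)	yes	IV-I	POSITIVE
4	CRC	Colorectal	5.00%	MSH2	c.340G>T	p.E114*	Neg, NA	MSI-High	Loss of MSH2 and MSH6	MSH2:c.657delA (p.G220Efs*4)	yes	IV-I	POSITIVE
5	CRC	Colorectal	22.3%	MSH2	c.2041C>T	p.Q681*	Neg, NA	MSI-High	Loss of MSH2 and MSH6	MSH2:c.2260_2269del (p.S755Mfs*5)	yes	IV-I	POSITIVE
6	CRC	Colorectal	7.40%	MSH2	c.2459-12A>G		Neg, NA	MSI-High	Loss of MSH2 and MSH6	MSH2:c.2090G>T (p.C697F)	yes	IV-I	POSITIVE
7	CRC	Colorectal	3.50%	MSH2	c.1906G>C	p.A636P	Neg, NA	MSI-High	Loss of MSH2 and MSH6	MSH2:c.1861C>T (p.R621*)	yes	IV-I	POSITIVE
8	CRC	Colorectal	3.90%	MSH2	c.942+3A>T		Neg, NA	MSI-High	Loss of MSH2 and MSH6	MSH2:c.2131C>T (p.R711*);MSH2 single-copy loss	yes;yes	IV-I	POSITIVE
9	CRC	Colorectal	32.10%	MSH2	c.2038C>T	p.R680*	Neg, NA	MSI-High	Loss of MSH2 and MSH6	MSH2:c.2362dupA (p.T788Nfs*11)	yes	IV-I	POSITIVE
10	CRC	Colorectal	4.30%	MSH2	EXON7 copy gain (5 copies)		Neg, NA	MSI-High	Loss of MSH2 and MSH6	MSH2:c.1216C>T (p.R406*)	yes	IV-I	POSITIVE
11	CRC	Colorectal	20.1%	MSH2	c.2131C>T	p.R711*	Neg, NA	MSI-High	Loss of MSH2 and MSH6	MSH2 single-copy loss	yes	IV-I	POSITIVE
12	CRC	Colorectal	9.7%	MSH2	c.2314delA	p.T772Qfs*40	Neg, NA	MSI-High	Loss of MSH2 and MSH6	MSH2 single-copy loss	yes	IV-I	POSITIVE
13	CRC	Colorectal	2.50%	MSH6	c.10C>T	p.Q4*	Neg, NA	MSI-High	Loss of MSH6	MSH6:c.1810G>T (p.E604*);MSH6:c.3261delC (p.F1088Sfs*2)	yes;yes	V-I	POSITIVE
14	CRC	Colorectal	6.40%	MSH6	c.2230dupG	p.E744Gfs*12	Neg, NA	MSI-High	Loss of MSH6	MSH6:c.3261dupC (p.F1088Lfs*5)	yes	V-I	POSITIVE
15	CRC	Colorectal	11.60%	PMS2	c.137G>T	p.S46I	Neg, NA	MSI-High	Loss of PMS2	PMS2:c.163+2T>C;PMS2:c.2444C>T (p.S815L)	yes;yes	III-III	POSITIVE
16	CRC	Endometrial and Colorectal	14.40%	PMS2	c.2192_2196delTAACT	p.L731Cfs*3	Neg, NA	MSI-High	Loss of PMS2	PMS2:c.2444C>T (p.S815L)	yes	III-III	POSITIVE
17	CRC		2.70%	PMS2	5'UTR_EX15del		Neg, NA	MSI-High	Loss of PMS2 and partial loss MSH6**	PMS2:c.1663C>T (p.Q555*)	yes	IHC pattern not included in assessment	NON_POSITIVE
18	CRC		3.20%	PMS2	c.861_864delACAG	p.R287Sfs*19	Neg, NA	MSI-High	Loss of PMS2	None Detected		I-V	NON_POSITIVE
19	CRC		>50%	MSH2	c.1226_1227delAG	p.Q409Rfs*7	Neg, NA	MSI-High	Loss of MSH2 and MSH6	None Detected		I-V	NON_POSITIVE
20	CRC		20.3%	MLH1	c.2142G>A	p.W714*	Neg, NA	MSI-High	Loss of MLH1 and PMS2	None Detected		I-V	NON_POSITIVE
21	CRC		11.80%	PMS2	c.736_741delCCCCCTins11	p.P246Cfs*3	Neg, NA	MSI-High	Loss of PMS2			I-V	NON_POSITIVE
22	CRC		45.10%	MLH1	c.677G>A	p.R226Q	Neg, NA	MSI-High	Loss of MLH1, MSH6, and PMS2	None Detected		I-V	NON_POSITIVE
23	CRC		0.60%	PMS2	c.861_864delACAG	p.R287Sfs*19	Neg, NA	MSI-High	Loss of PMS2	PMS2:5'UTR_EX5del	yes	I-II	NON_POSITIVE
24	CRC		1.60%	PMS2	c.2445+1G>T		Neg, NA	MSI-High	Loss of PMS2	PMS2:c.2404C>T (p.R802*)	yes	I-II	NON_POSITIVE
25	CRC		1.30%	MSH6	c.3261delC	p.F1088Sfs*2	Neg, MLH1 promoter hyper methylation	MSI-High	Loss of MSH6	MSH6:c.538delG (p.D180Mfs*4)	yes	I-II, I-IV	NON_POSITIVE
26	CRC		1.20%	PMS2	EXON10del		Neg, NA	MSI-High	Loss of PMS2	PMS2:c.2174+1G>A	yes	I-II	NON_POSITIVE
27	CRC		27.50%	MLH1	c.292G>C	p.G98R	Neg, NA	MSI-High	Normal IHC	MLH1:c.3G>C (p.M1?)	yes	I-VII	NON_POSITIVE
28	CRC		38.30%	MLH1	c.301G>C	p.G101R	Neg, NA	MSI-High	Normal IHC	MLH1:c.199G>A (p.G67R)	yes	I-VII	NON_POSITIVE
29	CRC		14.60%	MSH6	c.10C>T	p.Q4*	Neg, NA	MSI-High	Normal IHC	MSH6:c.3622_3625delTCTC (p.S1208Wfs*7)	yes	I-VII	NON_POSITIVE
30	EC	Endometrial	5.90%	MSH2	EX12_15del		Neg	MSI-High	loss of MSH2 and MSH6	MSH2:c.1697dupA (p.N566Kfs*2)	yes	IV-I	POSITIVE
31	EC	Endometrial	6.70%	MSH2	c.226C>T	p.Q76*	Neg	MSI-High	loss of MSH2 and MSH6	MSH2:c.2334C>A (p.C778*)	yes	IV-I	POSITIVE
32	EC	Endometrial	4.20%	MSH6	c.3436C>T	p.Q1146*	Neg	MSI-High	loss of MSH6	MSH6:c.3238_3239delCT (p.L1080Vfs*12)	yes	V-I	POSITIVE
33	EC	Endometrial	3.00%	MSH6	c.3416G>T	p.G1139V	Neg	MSI-High	loss of MSH6	MSH6:c.3261delC (p.F1088Sfs*2)	yes	V-I	POSITIVE
34	EC	Endometrial	2.50%	MSH6	c.3984_3987dupGTCA	p.L1330Vfs*12	Neg	MSI-High	loss of MSH6	MSH6:c.2933delA (p.Q978Rfs*19)	yes	V-I	POSITIVE
35	EC	Endometrial	4.00%	PMS2	c.736_741delCCCCCTins11	p.P246Cfs*3	Neg	MSI-High	loss of PMS2	PMS2:c.1376_1405del30 (p.S459*)	yes	III-I	POSITIVE
36	EC	Endometrial	2.90%	PMS2	c.2192_2196del	p.L731Cfs*3	Neg	MSI-High	loss of PMS2	PMS2 one copy loss	yes	III-I	POSITIVE
37	EC	Endometrial	7.00%	MSH2	c.309T>A	p.Y103*	Neg	MSI-High	loss of MSH2 and equivocal MSH6**	MSH2 single copy loss	yes	IHC pattern not included in assessment	NON_POSITIVE
38	EC	Endometrial	2.00%	PMS2	c.2117delA	p.K706Sfs*19	Positive	MSI-High	loss of MLH1 and PMS2	None Detected		I-II, I-III, or I-IV	NON_POSITIVE
39	EC	Endometrial	5.40%	PMS2	c.767delG	p.G256Vfs*2	Neg	MSI-High	loss of PMS2 and MSH6	None Detected		I-IV	NON_POSITIVE
40	EC	Endometrial	2.4%	MSH6	c.3261dupC	p.F1088Lfs*5	Neg	MSI-High	loss of MSH6	None Detected		I-II or I-IV	NON_POSITIVE
41	EC	Endometrial	5.60%	MSH6	c.3261delC	p.F1088Sfs*2	Neg	MSI-High	loss of MSH6	None Detected		I-IV	NON_POSITIVE
42	EC	Endometrial	6.20%	MSH6	c.3939_3957dup19	p.A1320Sfs*5	Neg	MSI-High	loss of MSH6	None Detected		I-IV	NON_POSITIVE
43	EC	Endometrial	4.70%	PMS2	c.137G>T	p.S46I	Neg	MSI-S	loss of PMS2	None Detected		I-IV or I-V	NON_POSITIVE
44	EC	Endometrial	2.70%	MSH6	c.10C>T	p.Q4*	N/A	MSI-High	Loss of MSH6	None Detected		I-IV	NON_POSITIVE
45	EC	Endometrial	3.30%	PMS2	c.861_864delACAG	p.R287Sfs*19	Neg	MSI-High	loss of PMS2	PMS2:c.404T>C (p.L135P)	no	I-IV	NON_POSITIVE
46	EC	Endometrial	3.10%	PMS2	c.137G>T	p.S46I	Neg	MSI-High	loss of PMS2	PMS2:c.163+5G>A	no	I-IV	NON_POSITIVE
47	EC	Endometrial	14.80%	MSH2	c.2152C>T	p.Q718*	Neg	MSI-High	loss of MSH2 and MSH6	MSH2:c.1241_1255del15 (p.L414_I418del)	no	I-IV	NON_POSITIVE
48	EC	Endometrial	2.00%	PMS2	EX9_10del		Neg	MSI-High	loss of PMS2	PMS2 single copy loss	yes	I-II	NON_POSITIVE
49	EC	Endometrial	2.4%	MSH6	c.3268_3274delGAGCTTA	p.E1090Kfs*23	N/A	MSI-High	Loss of MSH6	MSH6:c.3731T>G (p.L1244*)	yes	I-II	NON_POSITIVE
50	EC	Endometrial	7.00%	MSH6	c.10C>T	p.Q4*	Neg	None	loss of MSH6	MSH6:c.2386G>T (p.E796*)	yes	I-V	NON_POSITIVE
51	EC	Endometrial	5.70%	MSH2	c.1906G>C	p.A636P	Neg	None	loss of MSH2 and MSH6	MSH2:c.1861C>T (p.R621*)	yes	I-V	NON_POSITIVE
52	EC	Endometrial	5.10%	MSH6	c.742C>T	p.R248*	Neg	MSI-S	loss of MSH6	MSH6:c.3261delC (p.F1088Sfs*2)	yes	I-V	NON_POSITIVE
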