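subject_id	gene	chrom	pos	ref	alt	consequence	quality	max_ext_maf	control_allele_count	clinvar_class	in_repeat_region	in_last_exon	functional_deleterious	expected_step	expected_verdict	note
S01	POT1	chr2	100137	A	G	missense	90	0	0	NONE	0	0	0	1	ELIMINATED	low quality
S02	NBN	chr3	100274	A	G	frameshift	149.9	0	0	NONE	0	0	0	1	ELIMINATED	just below threshold
S03	BRCA2	chr4	100411	A	G	missense	90	0	0	P	0	0	0	1	ELIMINATED	ClinVar P does not rescue step 1
S04	CHEK2	chr5	100548	A	G	stop_gain	10	0	0	LP	0	0	0	1	ELIMINATED	LP does not rescue step 1
S05	OCA2	chr6	100685	A	G	missense	120	0	0	VUS	0	0	1	1	ELIMINATED	functional does not rescue step 1
S06	TYRP1	chr7	100822	A	G	synonymous	0	0	0	NONE	0	0	0	1	ELIMINATED	zero quality
S07	ATM	chr8	100959	A	G	utr_or_intergenic	200	0	0	NONE	0	0	0	2	ELIMINATED	out of bait
S08	ACD	chr9	101096	A	G	utr_or_intergenic	150	0.5	99	B	1	0	0	2	ELIMINATED	first matching step only
S09	MC1R	chr10	101233	A	G	utr_or_intergenic	151	0	0	VUS	0	0	0	2	ELIMINATED	VUS is not a rescue
S10	CDKN2A	chr11	101370	A	G	utr_or_intergenic	1000	0.002	2	NONE	0	0	0	2	ELIMINATED	
S11	POT1	chr12	101507	A	G	intronic_noncanonical	300	0	0	NONE	0	0	0	3	ELIMINATED	
S12	NBN	chr13	101644	A	G	intronic_noncanonical	150	0.9	50	LB	1	0	0	3	ELIMINATED	short-circuit at 3
S13	BRCA2	chr14	101781	A	G	intronic_noncanonical	200	0	0	NONE	0	0	0	3	ELIMINATED	
S14	CHEK2	chr15	101918	A	G	intronic_noncanonical	400	0.001	1	NONE	0	0	0	3	ELIMINATED	
S15	OCA2	chr16	102055	A	G	missense	200	0.0031	0	NONE	0	0	0	4	ELIMINATED	just above 0.003
S16	TYRP1	chr17	102192	A	G	missense	200	0.5	0	NONE	0	0	0	4	ELIMINATED	common
S17	ATM	chr18	102329	A	G	synonymous	200	0.01	0	NONE	0	0	0	4	ELIMINATED	MAF precedes synonymous
S18	ACD	chr19	102466	A	G	frameshift	200	0.2	99	B	1	1	0	4	ELIMINATED	first match is 4
S19	MC1R	chr20	102603	A	G	canonical_splice	200	0.004	0	NONE	0	0	0	4	ELIMINATED	
S20	CDKN2A	chr1	102740	A	G	missense	200	0	3	NONE	0	0	0	5	ELIMINATED	ac 3 > 2
S21	POT1	chr2	102877	A	G	missense	200	0.003	40	NONE	0	0	0	5	ELIMINATED	maf exactly at threshold passes 4
S22	NBN	chr3	103014	A	G	stop_gain	200	0	10	NONE	0	0	0	5	ELIMINATED	truncating but control-frequent
S23	BRCA2	chr4	103151	A	G	synonymous	200	0	3	NONE	0	0	0	5	ELIMINATED	5 precedes 6
S24	CHEK2	chr5	103288	A	G	missense	200	0.001	100	VUS	0	0	0	5	ELIMINATED	
S25	OCA2	chr6	103425	A	G	synonymous	200	0	0	NONE	0	0	0	6	ELIMINATED	
S26	TYRP1	chr7	103562	A	G	synonymous	150	0.002	2	NONE	0	0	0	6	ELIMINATED	boundaries pass 1,4,5
S27	ATM	chr8	103699	A	G	synonymous	200	0	0	VUS	0	0	0	6	ELIMINATED	
S28	ACD	chr9	103836	A	G	synonymous	999	0	1	LB	1	0	0	6	ELIMINATED	6 precedes 7,8
S29	MC1R	chr10	103973	A	G	missense	200	0	0	B	0	0	0	7	ELIMINATED	
S30	CDKN2A	chr11	104110	A	G	missense	200	0	0	LB	0	0	0	7	ELIMINATED	
S31	POT1	chr12	104247	A	G	inframe_indel	200	0	0	B	1	0	0	7	ELIMINATED	7 precedes 8
S32	NBN	chr13	104384	A	G	frameshift	200	0	0	LB	0	1	0	7	ELIMINATED	7 precedes 9
S33	BRCA2	chr14	104521	A	G	missense	200	0	0	NONE	1	0	0	8	ELIMINATED	
S34	CHEK2	chr15	104658	A	G	inframe_indel	200	0	0	VUS	1	0	0	8	ELIMINATED	
S35	OCA2	chr16	104795	A	G	frameshift	200	0	0	NONE	1	1	0	8	ELIMINATED	8 precedes 9
S36	TYRP1	chr17	104932	A	G	canonical_splice	151	0.001	2	NONE	1	0	0	8	ELIMINATED	
S37	ATM	chr18	105069	A	G	frameshift	200	0	0	NONE	0	1	0	9	ELIMINATED	
S38	ACD	chr19	105206	A	G	stop_gain	200	0	0	NONE	0	1	0	9	ELIMINATED	stop-gain too
S39	MC1R	chr20	105343	A	G	frameshift	150	0.003	2	VUS	0	1	0	9	ELIMINATED	all boundaries pass
S40	CDKN2A	chr1	105480	A	G	stop_gain	500	0.0001	1	NONE	0	1	0	9	ELIMINATED	
S41	POT1	chr2	105617	A	G	missense	200	0.5	0	P	0	0	0		RETAINED_PLP	P rescues past 4
S42	NBN	chr3	105754	A	G	missense	200	0	99	LP	0	0	0		RETAINED_PLP	LP rescues past 5
S43	BRCA2	chr4	105891	A	G	synonymous	200	0	0	P	0	0	0		RETAINED_PLP	P rescues past 6
S44	CHEK2	chr5	106028	A	G	missense	200	0	0	LP	1	0	0		RETAINED_PLP	LP rescues past 8
S45	OCA2	chr6	106165	A	G	frameshift	200	0	0	LP	0	1	0		RETAINED_PLP	LP rescues past 9 (last exon)
S46	TYRP1	chr7	106302	A	G	utr_or_intergenic	200	0	0	P	0	0	0		RETAINED_PLP	P rescues past 2
S47	ATM	chr8	106439	A	G	intronic_noncanonical	200	0	0	LP	0	0	0		RETAINED_PLP	LP rescues past 3
S48	ACD	chr9	106576	A	G	missense	200	0.9	50	VUS	1	0	1		RETAINED_PLP	functional rescues past 4,5,8
S49	MC1R	chr10	106713	A	G	stop_gain	200	0	0	P	0	1	0		RETAINED_PLP	P rescues last-exon stop-gain
S50	CDKN2A	chr11	106850	A	G	inframe_indel	200	0	0	LP	0	0	0		RETAINED_PLP	in-frame del via ClinVar rescue
S51	POT1	chr12	106987	A	G	frameshift	200	0	0	NONE	0	0	0		RETAINED_PLP	truncating survivor
S52	NBN	chr13	107124	A	G	frameshift	150	0	0	NONE	0	0	0		RETAINED_PLP	quality exactly 150 retained
S53	BRCA2	chr14	107261	A	G	stop_gain	200	0.003	2	NONE	0	0	0		RETAINED_PLP	boundary MAF/ac retained
S54	CHEK2	chr15	107398	A	G	canonical_splice	200	0	0	NONE	0	0	0		RETAINED_PLP	splice site +/-1-2
S55	OCA2	chr16	107535	A	G	cnv_frameshifting	200	0	0	NONE	0	0	0		RETAINED_PLP	frameshifting CNV
S56	TYRP1	chr17	107672	A	G	missense	200	0	0	VUS	0	0	1		RETAINED_PLP	functionally deleterious missense
S57	ATM	chr18	107809	A	G	missense	200	0	0	NONE	0	0	0		RETAINED_VUS	plain missense survivor
S58	ACD	chr19	107946	A	G	missense	200	0.002	2	VUS	0	0	0		RETAINED_VUS	ClinVar VUS survivor
S59	MC1R	chr20	108083	A	G	inframe_indel	200	0	0	NONE	0	0	0		RETAINED_VUS	in-frame indel is VUS
S60	CDKN2A	chr1	108220	A	G	cnv_other	200	0	0	NONE	0	0	0		RETAINED_VUS	non-frameshifting CNV is VUS
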