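# Transcription of the published per-virus summary table (values as printed).
# unknown column holds the full unresolved count; orphan holds the parenthesised
# ORFan subset where printed, empty where the source row prints no parentheses.
genome_id	accession	group	identity_ancestor_pct	size_kb	duplication	lgt	insertion	total_gain	loss	excision	total_loss	unknown	orphan	translocation	genomic_events
Mimivirus	NC_014649.1	mimivirus	99	1182	5	0	1	6	7	0	7	0		0	13
Mamavirus	JF801956.1	mimivirus	99	1192	5	0	0	5	7	0	7	3		8	23
Hirudovirus	KF493731	mimivirus	99	1181	3	0	1	4	6	0	6	0		1	11
Terra2	NC_023639	mimivirus	99	1169	10	3	2	15	19	1	20	3		3	41
Megavirus Chiliensis	NC_016072.1	megavirus	98	1259	9	1	2	11	5	0	5	4	0	0	20
Megavirus lba	NC_020232	megavirus	97	1231	9	0	1	10	24	0	24	4	0	1	39
Megavirus courdo11	JX975216	megavirus	98	1246	6	1	3	10	15	1	16	10	2	0	36
Megavirus terra1	NC_023640	megavirus	99	1245	12	0	1	13	8	1	9	1	0	0	23
OtV1	NC_013288	ostreococcus	88	192	3	5	0	8	9	0	9	4	1	0	21
OtV2	NC_014789.1	ostreococcus	87	184	1	13	0	14	12	0	12	7	4	0	33
OsV5	NC_010191	ostreococcus	89	185	1	5	0	6	4	0	4	7	4	0	17
OlV1	NC_014766	ostreococcus	85	194	1	11	0	12	8	0	8	4	2	0	24
OtVRT-2011	JN225873	ostreococcus	92	190	0	12	0	12	7	0	7	18	9	0	37
MpV SP1	JF974320	micromonas	82	173	1	8	0	9	20	0	20	14	3	0	43
MpV1	NC_014767	micromonas	83	184	0	8	0	8	16	0	16	27	16	0	51
MpV PL1	HQ633072	micromonas	81	197	12	9	0	21	17	0	17	23	15	0	61
Nys-1	JX997183	chlorella	98	348	3	0	3	6	13	2	15	6	1	0	27
NY2A	NC_009898	chlorella	94	369	16	4	6	26	14	1	15	7	5	0	48
AR158	NC_009899	chlorella	99	345	7	3	2	12	9	4	13	2	1	0	27
IL-5-2s1	JX997170	chlorella	99	345	1	0	1	2	3	3	6	3	0	0	11
MA-1D	JX997172	chlorella	99	340	0	0	2	2	9	6	15	2	1	0	20
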