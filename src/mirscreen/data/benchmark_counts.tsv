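gene	program	predicted	tested	positive
MXI1	TargetScan	79	71	11
MXI1	TargetScanS	117	104	14
MXI1	PITA	29	15	0
MXI1	microT_v3.0	27	26	3
MXI1	PicTar	14	11	3
MXI1	miRanda	190	165	22
MXI1	miRDB	26	25	7
MXI1	NBmiRTar	126	77	5
MXI1	EIMMo	47	43	8
TP53	TargetScan	53	21	4
TP53	TargetScanS	68	31	4
TP53	PITA	82	19	2
TP53	microT_v3.0	10	8	1
TP53	PicTar	0	0	0
TP53	miRanda	8	5	1
TP53	miRDB	10	9	2
TP53	NBmiRTar	124	34	6
TP53	EIMMo	9	7	1
PTEN	TargetScan	115	26	5
PTEN	TargetScanS	177	37	12
PTEN	PITA	40	6	0
PTEN	microT_v3.0	71	20	7
PTEN	PicTar	14	4	0
PTEN	miRanda	243	48	14
PTEN	miRDB	59	15	8
PTEN	NBmiRTar	181	30	4
PTEN	EIMMo	92	23	8
CYP3A4	TargetScan	43	32	4
CYP3A4	TargetScanS	74	43	4
CYP3A4	PITA	43	7	0
CYP3A4	microT_v3.0	0	0	0
CYP3A4	PicTar	0	0	0
CYP3A4	miRanda	0	0	0
CYP3A4	miRDB	18	10	1
CYP3A4	NBmiRTar	74	10	3
CYP3A4	EIMMo	3	2	0
POT1	TargetScan	45	41	5
POT1	TargetScanS	82	67	8
POT1	PITA	23	12	0
POT1	microT_v3.0	6	6	0
POT1	PicTar	0	0	0
POT1	miRanda	25	21	1
POT1	miRDB	19	18	1
POT1	NBmiRTar	67	40	2
POT1	EIMMo	0	0	0
TRF2	TargetScan	50	43	7
TRF2	TargetScanS	41	34	8
TRF2	PITA	65	24	1
TRF2	microT_v3.0	0	0	0
TRF2	PicTar	1	1	0
TRF2	miRanda	79	67	11
TRF2	miRDB	8	8	0
TRF2	NBmiRTar	113	67	8
TRF2	EIMMo	8	7	2
FSCN1	TargetScan	47	38	8
FSCN1	TargetScanS	38	31	9
FSCN1	PITA	27	10	1
FSCN1	microT_v3.0	3	3	2
FSCN1	PicTar	0	0	0
FSCN1	miRanda	8	7	1
FSCN1	miRDB	8	4	3
FSCN1	NBmiRTar	133	73	8
FSCN1	EIMMo	8	7	5
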