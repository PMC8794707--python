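target	motive	condition	score	category
AXL	Cell growth and Proliferation	solo	33	-
AXL	Cell growth and Proliferation	combination	33	-
AXL	Apoptosis evasion	solo	7	-
AXL	Apoptosis evasion	combination	40	-
AXL	Angiogenesis	solo	30	-
AXL	Angiogenesis	combination	19	-
AXL	Immune evasion	solo	54	+
AXL	Immune evasion	combination	81	+++
AXL	Metastasis and Invasion	solo	48	+
AXL	Metastasis and Invasion	combination	63	+
FLT1	Cell growth and Proliferation	solo	31	-
FLT1	Cell growth and Proliferation	combination	34	-
FLT1	Apoptosis evasion	solo	9	-
FLT1	Apoptosis evasion	combination	39	-
FLT1	Angiogenesis	solo	56	+
FLT1	Angiogenesis	combination	59	+
FLT1	Immune evasion	solo	53	+
FLT1	Immune evasion	combination	79	+++
FLT1	Metastasis and Invasion	solo	29	-
FLT1	Metastasis and Invasion	combination	29	-
FLT3	Cell growth and Proliferation	solo	33	-
FLT3	Cell growth and Proliferation	combination	33	-
FLT3	Apoptosis evasion	solo	17	-
FLT3	Apoptosis evasion	combination	38	-
FLT3	Angiogenesis	solo	20	-
FLT3	Angiogenesis	combination	22	-
FLT3	Immune evasion	solo	19	-
FLT3	Immune evasion	combination	74	++
FLT3	Metastasis and Invasion	solo	28	-
FLT3	Metastasis and Invasion	combination	29	-
FLT4	Cell growth and Proliferation	solo	31	-
FLT4	Cell growth and Proliferation	combination	34	-
FLT4	Apoptosis evasion	solo	10	-
FLT4	Apoptosis evasion	combination	39	-
FLT4	Angiogenesis	solo	32	-
FLT4	Angiogenesis	combination	20	-
FLT4	Immune evasion	solo	17	-
FLT4	Immune evasion	combination	73	++
FLT4	Metastasis and Invasion	solo	28	-
FLT4	Metastasis and Invasion	combination	27	-
KDR	Cell growth and Proliferation	solo	43	-
KDR	Cell growth and Proliferation	combination	42	-
KDR	Apoptosis evasion	solo	12	-
KDR	Apoptosis evasion	combination	40	-
KDR	Angiogenesis	solo	58	+
KDR	Angiogenesis	combination	63	+
KDR	Immune evasion	solo	31	-
KDR	Immune evasion	combination	72	++
KDR	Metastasis and Invasion	solo	34	-
KDR	Metastasis and Invasion	combination	34	-
KIT	Cell growth and Proliferation	solo	40	-
KIT	Cell growth and Proliferation	combination	43	-
KIT	Apoptosis evasion	solo	19	-
KIT	Apoptosis evasion	combination	37	-
KIT	Angiogenesis	solo	51	+
KIT	Angiogenesis	combination	61	+
KIT	Immune evasion	solo	20	-
KIT	Immune evasion	combination	74	++
KIT	Metastasis and Invasion	solo	31	-
KIT	Metastasis and Invasion	combination	29	-
MERTK	Cell growth and Proliferation	solo	24	-
MERTK	Cell growth and Proliferation	combination	28	-
MERTK	Apoptosis evasion	solo	6	-
MERTK	Apoptosis evasion	combination	38	-
MERTK	Angiogenesis	solo	24	-
MERTK	Angiogenesis	combination	21	-
MERTK	Immune evasion	solo	52	+
MERTK	Immune evasion	combination	81	+++
MERTK	Metastasis and Invasion	solo	28	-
MERTK	Metastasis and Invasion	combination	31	-
MET	Cell growth and Proliferation	solo	40	-
MET	Cell growth and Proliferation	combination	38	-
MET	Apoptosis evasion	solo	11	-
MET	Apoptosis evasion	combination	45	-
MET	Angiogenesis	solo	23	-
MET	Angiogenesis	combination	17	-
MET	Immune evasion	solo	14	-
MET	Immune evasion	combination	82	+++
MET	Metastasis and Invasion	solo	77	++
MET	Metastasis and Invasion	combination	71	++
NTRK2	Cell growth and Proliferation	solo	53	+
NTRK2	Cell growth and Proliferation	combination	44	-
NTRK2	Apoptosis evasion	solo	7	-
NTRK2	Apoptosis evasion	combination	38	-
NTRK2	Angiogenesis	solo	22	-
NTRK2	Angiogenesis	combination	22	-
NTRK2	Immune evasion	solo	16	-
NTRK2	Immune evasion	combination	74	++
NTRK2	Metastasis and Invasion	solo	49	+
NTRK2	Metastasis and Invasion	combination	63	+
RET	Cell growth and Proliferation	solo	31	-
RET	Cell growth and Proliferation	combination	31	-
RET	Apoptosis evasion	solo	49	+
RET	Apoptosis evasion	combination	61	+
RET	Angiogenesis	solo	22	-
RET	Angiogenesis	combination	22	-
RET	Immune evasion	solo	17	-
RET	Immune evasion	combination	74	++
RET	Metastasis and Invasion	solo	47	+
RET	Metastasis and Invasion	combination	61	+
ROS1	Cell growth and Proliferation	solo	20	-
ROS1	Cell growth and Proliferation	combination	31	-
ROS1	Apoptosis evasion	solo	7	-
ROS1	Apoptosis evasion	combination	40	-
ROS1	Angiogenesis	solo	22	-
ROS1	Angiogenesis	combination	20	-
ROS1	Immune evasion	solo	15	-
ROS1	Immune evasion	combination	73	++
ROS1	Metastasis and Invasion	solo	22	-
ROS1	Metastasis and Invasion	combination	28	-
TEK	Cell growth and Proliferation	solo	32	-
TEK	Cell growth and Proliferation	combination	31	-
TEK	Apoptosis evasion	solo	9	-
TEK	Apoptosis evasion	combination	38	-
TEK	Angiogenesis	solo	48	+
TEK	Angiogenesis	combination	65	+
TEK	Immune evasion	solo	15	-
TEK	Immune evasion	combination	73	++
TEK	Metastasis and Invasion	solo	18	-
TEK	Metastasis and Invasion	combination	24	-
TYRO3	Cell growth and Proliferation	solo	23	-
TYRO3	Cell growth and Proliferation	combination	31	-
TYRO3	Apoptosis evasion	solo	6	-
TYRO3	Apoptosis evasion	combination	40	-
TYRO3	Angiogenesis	solo	21	-
TYRO3	Angiogenesis	combination	21	-
TYRO3	Immune evasion	solo	49	+
TYRO3	Immune evasion	combination	77	++
TYRO3	Metastasis and Invasion	solo	32	-
TYRO3	Metastasis and Invasion	combination	32	-
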