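entity	motive	score	category
cabozantinib	Apoptosis evasion	74	++
cabozantinib	Immune evasion	83	+++
cabozantinib	Angiogenesis	87	+++
cabozantinib	Metastasis and Invasion	87	+++
cabozantinib	Cell growth and Proliferation	81	+++
PD1 inhibitor	Apoptosis evasion	56	+
PD1 inhibitor	Immune evasion	83	+++
PD1 inhibitor	Angiogenesis	5	-
PD1 inhibitor	Metastasis and Invasion	20	-
PD1 inhibitor	Cell growth and Proliferation	26	-
cabozantinib+PD1 inhibitor	Apoptosis evasion	89	+++
cabozantinib+PD1 inhibitor	Immune evasion	89	+++
cabozantinib+PD1 inhibitor	Angiogenesis	86	+++
cabozantinib+PD1 inhibitor	Metastasis and Invasion	85	+++
cabozantinib+PD1 inhibitor	Cell growth and Proliferation	81	+++
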