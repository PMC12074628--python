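species_scope	codon_index	ref_codon	alt_codon	status	evidence
Rnor,Rrat	7	AGC	GGC	novel	newly identified; near cytoplasmic interface
Rnor,Rrat	12	CGG	CGA	known_other	silent; codon-usage background in R. rattus
Rnor,Rrat	28	CAC	CAG	novel	newly identified in rodents; H28Q confers warfarin resistance in human VKORC1
Rnor,Rrat	35	CGC	CGT	known_other	silent; codon-usage background
Rnor,Rrat	36	AAT	CAT	novel	newly identified; ER-luminal region
Rnor,Rrat	41	GCG	GCA	known_other	silent; codon-usage background
Rnor,Rrat	42	CTC	CCC	novel	newly identified; close to catalytic Cys43
Rnor,Rrat	59	TGG	AGG	resistance_associated	W59R; in vivo anticoagulant resistance in brown rat
Rnor,Rrat	61	CGG	TGG	resistance_associated	R61W; anticoagulant resistance
Rnor,Rrat	82	ATA	ATT	known_other	silent; codon-usage background
Rrat	90	ATA	TTA	species_fixed	I90L; wild-type codon 90 is Leu in R. rattus, Ile in R. norvegicus
Rnor,Rrat	94	TTA	CTA	known_other	silent; codon-usage background
Rnor,Rrat	96	TGC	GGC	novel	newly identified; near cytoplasmic interface
Rnor,Rrat	107	ATC	ATA	known_other	silent; codon-usage background
Rnor,Rrat	123	ATC	TTC	novel	I123F newly identified; in contact with ligand
Rnor,Rrat	123	ATC	AGC	known_other	I123S previously reported; AR-resistance association unknown
Rnor,Rrat	137	ACC	ACT	known_other	silent; codon-usage background
Rnor,Rrat	139	TAT	TTT	resistance_associated	Y139F; warfarin resistance, widespread in Europe
Rnor,Rrat	143	GCG	GCA	known_other	silent; codon-usage background
Mmus	78	CAA	CAC	novel	newly identified; anchor region of the cap domain
Mmus	85	TGC	CGC	novel	newly identified; membrane-exposed single cysteine
Mmus	87	TTC	TTA	novel	F87L newly identified; ring stacking with ligand side group
Mmus	128	TTA	TCA	resistance_associated	L128S; anticoagulant resistance in house mouse
Mmus	139	TAT	TGT	resistance_associated	Y139C; anticoagulant resistance in house mouse
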