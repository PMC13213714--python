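cohort	characteristic	category	count
IMvigor210	sex	female	50
IMvigor210	sex	male	194
IMvigor210	sex	NA	0
IMvigor210	smoking	former	145
IMvigor210	smoking	never	74
IMvigor210	smoking	current	25
IMvigor210	smoking	NA	0
IMvigor210	genomic_subtype	Hypermutated	1
IMvigor210	genomic_subtype	FGFR3	41
IMvigor210	genomic_subtype	RAS	7
IMvigor210	genomic_subtype	TP53/MDM2	99
IMvigor210	genomic_subtype	Triple negative	96
IMvigor210	tmb	<10	213
IMvigor210	tmb	>=10	31
IMvigor210	tmb	NA	0
IMvigor210	risk	low	121
IMvigor210	risk	high	123
IMvigor210	os	event	159
IMvigor210	os	censored	85
IMvigor210	os	NA	0
IMvigor210	ms_subtype	MUT1	150
IMvigor210	ms_subtype	MUT2	94
UC-GENOME	sex	female	47
UC-GENOME	sex	male	143
UC-GENOME	sex	NA	1
UC-GENOME	smoking	former	112
UC-GENOME	smoking	never	62
UC-GENOME	smoking	current	16
UC-GENOME	smoking	NA	1
UC-GENOME	genomic_subtype	Hypermutated	2
UC-GENOME	genomic_subtype	FGFR3	26
UC-GENOME	genomic_subtype	RAS	8
UC-GENOME	genomic_subtype	TP53/MDM2	105
UC-GENOME	genomic_subtype	Triple negative	50
UC-GENOME	tmb	<10	76
UC-GENOME	tmb	>=10	81
UC-GENOME	tmb	NA	34
UC-GENOME	risk	low	97
UC-GENOME	risk	high	94
UC-GENOME	os	event	78
UC-GENOME	os	censored	85
UC-GENOME	os	NA	28
UC-GENOME	ms_subtype	MUT1	63
UC-GENOME	ms_subtype	MUT2	128
TCGA	sex	female	108
TCGA	sex	male	304
TCGA	sex	NA	0
TCGA	smoking	former	198
TCGA	smoking	never	111
TCGA	smoking	current	90
TCGA	smoking	NA	13
TCGA	genomic_subtype	Hypermutated	1
TCGA	genomic_subtype	FGFR3	44
TCGA	genomic_subtype	RAS	30
TCGA	genomic_subtype	TP53/MDM2	199
TCGA	genomic_subtype	Triple negative	138
TCGA	tmb	<10	315
TCGA	tmb	>=10	97
TCGA	tmb	NA	0
TCGA	risk	low	173
TCGA	risk	high	239
TCGA	os	event	158
TCGA	os	censored	250
TCGA	os	NA	4
TCGA	ms_subtype	MUT1	161
TCGA	ms_subtype	MUT2	251
MSK2022	sex	female	296
MSK2022	sex	male	980
MSK2022	sex	NA	2
MSK2022	smoking	former	650
MSK2022	smoking	never	433
MSK2022	smoking	current	141
MSK2022	smoking	NA	54
MSK2022	genomic_subtype	Hypermutated	7
MSK2022	genomic_subtype	FGFR3	241
MSK2022	genomic_subtype	RAS	68
MSK2022	genomic_subtype	TP53/MDM2	629
MSK2022	genomic_subtype	Triple negative	333
MSK2022	tmb	<10	672
MSK2022	tmb	>=10	606
MSK2022	tmb	NA	0
MSK2022	risk	low	608
MSK2022	risk	high	670
MSK2022	os	event	445
MSK2022	os	censored	793
MSK2022	os	NA	40
MSK2022	ms_subtype	MUT1	833
MSK2022	ms_subtype	MUT2	445
MSK2015	sex	female	28
MSK2015	sex	male	54
MSK2015	sex	NA	1
MSK2015	smoking	former	44
MSK2015	smoking	never	22
MSK2015	smoking	current	16
MSK2015	smoking	NA	1
MSK2015	genomic_subtype	Hypermutated	1
MSK2015	genomic_subtype	FGFR3	39
MSK2015	genomic_subtype	RAS	11
MSK2015	genomic_subtype	TP53/MDM2	14
MSK2015	genomic_subtype	Triple negative	18
MSK2015	tmb	<10	61
MSK2015	tmb	>=10	22
MSK2015	tmb	NA	0
MSK2015	risk	low	46
MSK2015	risk	high	37
MSK2015	os	event	25
MSK2015	os	censored	43
MSK2015	os	NA	15
MSK2015	ms_subtype	MUT1	37
MSK2015	ms_subtype	MUT2	46
Tongji	sex	female	7
Tongji	sex	male	14
Tongji	sex	NA	0
Tongji	smoking	former	8
Tongji	smoking	never	7
Tongji	smoking	current	6
Tongji	smoking	NA	0
Tongji	genomic_subtype	Hypermutated	1
Tongji	genomic_subtype	FGFR3	1
Tongji	genomic_subtype	RAS	4
Tongji	genomic_subtype	TP53/MDM2	6
Tongji	genomic_subtype	Triple negative	9
Tongji	tmb	<10	19
Tongji	tmb	>=10	2
Tongji	tmb	NA	0
Tongji	risk	low	9
Tongji	risk	high	12
Tongji	os	event	6
Tongji	os	censored	15
Tongji	os	NA	0
Tongji	ms_subtype	MUT1	12
Tongji	ms_subtype	MUT2	9
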