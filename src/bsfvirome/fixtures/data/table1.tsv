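family	eve_name	locus_label	bga	best_hit	aa_pct	protein_class	coordinates
Partitiviridae	PartitiEVE	PT	1	Atrato Partiti-like virus 2	44.6	Capsid	JXPW01014295.1:343-1512
Partitiviridae	PartitiEVE	np	1	Atrato Partiti-like virus 2	49	Capsid	JXPW01121853.1:492-1707
Partitiviridae	PartitiEVE	np	2	Atrato Partiti-like virus 2	47.5	Capsid	VFFH01000694.1:2871386-2872788
Partitiviridae	PartitiEVE	PT	2	Atrato Partiti-like virus 2	54.8	Capsid	VFFH01002716.1:5535-6390
Partitiviridae	PartitiEVE	PT	3	Atrato Partiti-like virus 2	54.1	Capsid	LR899010.1:144460311-144461333
Parvoviridae	ParvoEVE	PR1	2	Clinch densovirus 1	66.7	Capsid	VFFH01002420.1:17403-17642
Parvoviridae	ParvoEVE	PR1	3	Densovirinae sp.	39.2	Capsid	LR899010.1:21909312-21909550
Parvoviridae	ParvoEVE	PR2	1	Haematobia irritans densovirus	45.3	Capsid	JXPW01295709.1:732-1063
Parvoviridae	ParvoEVE	np	2	Haematobia irritans densovirus	62.5	ORF1	VFFH01002716.1:27731-27993
Parvoviridae	ParvoEVE	np	2	Haematobia irritans densovirus	33.5	Capsid	VFFH01002716.1:22618-23330
Parvoviridae	ParvoEVE	PR2	3	Haematobia irritans densovirus	45.4	Capsid	LR899010.1:144484849-144485180
Parvoviridae	ParvoEVE	PR3	3	Lone star tick densovirus 1	45.8	ORF1	LR899014.1:3976151-3976299
Rhabdoviridae	RhabdoEVE	Rh	2	Entomophthora rhabdovirus A	55.1	RdRP	VFFH01000694.1:2885224-2885413
Totiviridae	TotiEVE	T1	1	Leptopilina boulardi toti-like virus	54.8	RdRP	JXPW01175605.1:2029-3362
Totiviridae	TotiEVE	T2	1	Leptopilina boulardi toti-like virus	34.6	Capsid	JXPW01052892.1:5735-9302
Totiviridae	TotiEVE	T1	1	Leptopilina boulardi toti-like virus	28.6	Capsid	JXPW01318472.1:69-1591
Totiviridae	TotiEVE	T3	1	Leptopilina boulardi toti-like virus	33.2	Capsid	JXPW01168285.1:326-1578
Totiviridae	TotiEVE	T1	2	Leptopilina boulardi toti-like virus	53	RdRP	VFFH01002277.1:524489-528239
Totiviridae	TotiEVE	T2	2	Leptopilina boulardi toti-like virus	30.4	Capsid	VFFH01001437.1:1443067-1446431
Totiviridae	TotiEVE	np	2	Leptopilina boulardi toti-like virus	38.5	Capsid	VFFH01001390.1:32171-33459
Totiviridae	TotiEVE	T3	2	Leptopilina boulardi toti-like virus	36.7	Capsid	VFFH01001777.1:322470-323680
Totiviridae	TotiEVE	T2	3	Leptopilina boulardi toti-like virus	30.4	Capsid	LR899013.1:31694664-31698028
Totiviridae	TotiEVE	T3	3	Leptopilina boulardi toti-like virus	36.8	Capsid	LR899014.1:10621516-10622714
Totiviridae	TotiEVE	np	1	Linepithema humile toti-like virus 1	38.9	Capsid	JXPW01318876.1:130-1861
Totiviridae	TotiEVE	T1	3	Dumyat virus	35.4	RdRP	LR899009.1:97208286-97212028
Totiviridae	TotiEVE	np	1	Dumyat virus	39.9	RdRP	JXPW01237450.1:1885-3346
Xinmoviridae	XinmoEVE	Xi	3	Lepidopteran anphe-related virus OKIAV50	61.6	RdRP	LR899013.1:111581535-111582826
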