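species	section	genome	ploidy	n_accessions	n_poly_within	n_poly_vs_wheat
Aegilops mutica	Amblyopyrum	TT	2	12	15617	33816
Aegilops comosa	Comopyrum	MM	2	14	16103	33305
Aegilops uniaristata	Comopyrum	NN	2	6	9190	33120
Aegilops caudata	Cylindropyrum	CC	2	7	11668	33433
Aegilops cylindrica	Cylindropyrum	DDCC	4	7	13147	30052
Aegilops biuncialis	Polyeides	UUMM	4	8	13040	33129
Aegilops columnaris	Polyeides	UUMM	4	7	13953	33419
Aegilops geniculata	Polyeides	MMUU	4	5	12412	33772
Aegilops kotschyii	Polyeides	SSUU	4	8	11658	33024
Aegilops neglecta	Polyeides	UUMM/UUMMNN	4 or 6	6	17373	33306
Aegilops peregrina	Polyeides	UUSS	4	9	16428	33127
Aegilops triuncialis	Polyeides	UUCC	4	17	17265	33378
Aegilops umbellulata	Polyeides	UU	2	15	15254	33365
Aegilops bicornis	Sitopsis	SS	2	5	17817	34085
Aegilops longissima	Sitopsis	SS	2	10	15835	33093
Aegilops searsii	Sitopsis	SS	2	13	10575	32804
Aegilops sharonensis	Sitopsis	SS	2	13	18220	33339
Aegilops speltoides	Sitopsis	SS	2	38	24524	32401
Aegilops crassa	Vertebrata	DDMM/DDMMMM	4 or 6	7	11798	30103
Aegilops juvenalis	Vertebrata	DDMMUU	6	5	12990	31120
Aegilops tauschii	Vertebrata	DD	2	22	21867	31212
Aegilops vavilovii	Vertebrata	DDSSMM	6	5	13893	30969
Aegilops ventricosa	Vertebrata	DDNN	4	11	14631	30211
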