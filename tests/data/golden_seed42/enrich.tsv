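phenotype	term	name	namespace	k	K	n	N	p	p_adj	significant	genes
synthetic_pain	T001	creatine and energy metabolism	BP	3	3	3	10	0.00833333	0.0333333	True	GENE01,GENE02,GENE03
synthetic_pain	T005	nucleotide binding	MF	2	3	3	10	0.183333	0.366667	False	GENE02,GENE03
synthetic_pain	T002	oxidant detoxification	BP	2	4	3	10	0.333333	0.444444	False	GENE01,GENE02
synthetic_pain	T003	apoptotic regulation	BP	1	3	3	10	0.708333	0.708333	False	GENE03
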