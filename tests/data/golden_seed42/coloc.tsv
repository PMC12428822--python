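phenotype	gene	layer	PP.H0	PP.H1	PP.H2	PP.H3	PP.H4	n_snps	window_kb	strong_coloc	low_coverage
synthetic_pain	GENE01	mQTL	1.15943e-83	1.62392e-29	7.13973e-58	2.2208e-32	1	60	500	True	False
synthetic_pain	GENE01	eQTL	8.49337e-177	1.62392e-29	5.23018e-151	2.2208e-32	1	60	1000	True	False
synthetic_pain	GENE01	pQTL	2.51262e-177	1.62392e-29	1.54726e-151	2.2208e-32	1	60	1000	True	False
synthetic_pain	GENE02	mQTL	3.72799e-119	6.6234e-75	5.62851e-45	1	2.23528e-38	60	500	False	False
synthetic_pain	GENE02	eQTL	4.3646e-221	6.6234e-75	6.58967e-147	1	1.19439e-48	60	1000	False	False
synthetic_pain	GENE02	pQTL	2.66411e-214	6.6234e-75	4.02227e-140	1	1.19439e-48	60	1000	False	False
synthetic_pain	GENE03	mQTL	1.87781e-113	3.26392e-54	5.75324e-60	1	1.11752e-38	60	500	False	False
synthetic_pain	GENE03	eQTL	9.77591e-191	3.26392e-54	2.99514e-137	1	1.11752e-38	60	1000	False	False
synthetic_pain	GENE03	pQTL	1.14546e-191	3.26392e-54	3.50945e-138	1	1.11752e-38	60	1000	False	False
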