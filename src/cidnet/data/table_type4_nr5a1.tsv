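feature_number	gene_symbol	direction	literature_annotation	regulation_by_tf
17400	GTF3C1	poor	Adriamycin/cytoxan resistance	up
5586	MYB	good	Good prognosis	down
6776	BATF	good	Poor prognostic predictor in B-cell lymphoma	up
5480	ESRRA	good	Poor prognosis	up
14511	FOXP1	poor	Good prognosis	down
878	ATF6B	good	Undefined	up
3113	GATA5	good	Undefined	up
2002	STAT2	poor	Good prognosis in carcinoid tumors	up
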