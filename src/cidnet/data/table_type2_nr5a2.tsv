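feature_number	gene_symbol	direction	literature_annotation	regulation_by_tf
2551	TAS2R8	poor	Undefined	unknown
16670	NR5A2	poor	Poor prognosis in PR(-) breast cancer	unknown
1761	ATG4D	poor	Enhancing chemoresistance	unknown
2967	ATP6V1H	poor	Early relapse in ER(+) BCs treated with tamoxifen	unknown
11875	EPHA2	poor	Poor prognosis (resistance to anti-HER (trastuzumab) therapy)	unknown
4013	A_23_P23110	poor	Undefined	unknown
10235	RAB40C	poor	Undefined	unknown
4332	MKL1	poor	Undefined	unknown
8615	GNAQ	poor	Undefined	unknown
7774	NRP2	poor	Poor prognosis in lung cancer and other cancers but not in breast cancer	unknown
7864	TNFSF9	poor	Undefined	unknown
14025	RHO	poor	Undefined	unknown
4337	GCDH	poor	Undefined	unknown
17978	MRLC2	poor	Undefined	unknown
22368	NDUFS2	good	Undefined	unknown
15037	PIP5K1A	good	Undefined	unknown
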