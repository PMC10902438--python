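ncbi_code	strain	ani_term	adult_prevalence_pct	adult_axp	infant_prevalence_pct	infant_axp
GCA_002838325.1	NRBB09	98.36	0.4	44.05	9.6	947.21
GCA_901212525.1	MC1	98.10	0.3	34.17	13.0	1270.70
GCA_902167875.1	B.breve_1_mod	98.08	0.3	29.29	9.7	948.86
GCA_020538685.1	MSK.23.130	98.10	0.3	26.85	12.6	1232.20
GCA_902167575.1	B.breve_2_mod	98.30	0.2	22.01	10.8	1057.37
GCA_002861455.1	UMB0915	98.10	0.2	21.97	12.2	1192.46
GCA_002838525.1	180W83	98.47	0.2	19.60	13.1	1285.29
GCA_003860285.1	lw01	98.10	0.2	19.53	12.4	1217.15
GCA_902167895.1	JG_Bg463	97.99	0.2	19.51	11.3	1105.42
GCA_014779815.1	142	98.14	0.2	17.09	11.4	1114.67
GCA_002838705.1	DRBB29	98.14	0.2	17.09	10.1	988.02
GCA_925285005.1	IM703	98.47	0.1	14.70	10.7	1058.10
GCA_002838365.1	NRBB50	98.46	0.1	14.70	12.2	1196.90
GCA_001990225.1	LMC520	98.32	0.1	14.68	9.9	972.65
GCA_000568955.1	PRL2012	98.52	0.1	12.26	10.5	1036.05
GCA_000247755.2	CECT 7263	98.47	0.1	12.25	10.7	1052.78
GCA_015547895.1	BSD2780061688	98.38	0.1	12.24	10.6	1038.89
GCA_013267755.1	JTL	98.62	0.1	9.82	10.6	1045.76
GCA_002838505.1	DRBB28	98.52	0.1	9.81	10.2	1001.59
GCA_000569015.1	JCM 7019	98.13	0.1	9.77	7.7	759.46
GCA_002914865.1	LMG S-29190	98.59	0.1	7.36	10.7	1051.87
GCA_002838645.1	NRBB20	98.55	0.1	7.36	8.4	832.74
GCA_902505445.1	LH_24	98.51	0.1	7.35	9.9	972.43
GCA_002838385.1	NRBB52	98.50	0.1	7.35	8.5	834.51
GCA_003813065.1	FDAARGOS_561	98.50	0.1	7.35	9.2	902.33
GCA_000220135.1	UCC2003	98.48	0.1	7.35	8.6	847.26
GCA_000226175.2	DPC 6330	98.46	0.1	7.35	8.6	850.29
GCA_002838425.1	NRBB56	98.40	0.1	7.34	8.5	836.82
GCA_002838345.1	NRBB57	98.59	0.0	4.91	8.6	848.17
GCA_009931415.1	JR01	98.56	0.0	4.90	9.6	949.16
GCA_000568975.1	JCM 7017	98.51	0.0	4.90	8.5	836.71
GCA_000411435.1	HPH0326	98.44	0.0	4.90	8.7	859.76
GCA_001189355.1	BBRI4	98.43	0.0	4.90	8.5	837.08
GCA_024760465.1	1101A	98.42	0.0	4.90	8.6	847.77
GCA_002838225.1	DRBB26	98.41	0.0	4.90	8.7	853.07
GCA_002838485.1	215W447a	98.50	0.0	2.45	8.2	807.57
GCA_002838465.1	017W439	98.57	0.0	0.00	7.2	713.28
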