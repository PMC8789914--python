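study	hr	ci_low	ci_high	n
GSE3141	1.10	0.51	2.38	53
GSE8894	1.10	0.54	2.25	75
GSE19188	0.61	0.23	1.61	24
GSE29013	1.20	0.35	4.18	25
GSE50081	1.06	0.32	3.48	42
GSE42127	0.56	0.21	1.51	43
TCGA-LUSC-test	1.60	1.05	2.44	247
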