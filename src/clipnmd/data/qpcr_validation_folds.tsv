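gene	qpcr_fold	qpcr_sd	array_fold	p_value	section	cryptic_exon_confirmed	robust_3utr_cluster
Dlg3	3.85	0.84	3.39	0.001	larger	yes	no
Dzip1	3.79	0.29	2.73	0.001	larger	yes	no
Dtd1	2.40	0.43	2.25	0.001	larger	no	no
Rasgrp2	3.64	0.39	2.23	0.001	larger	no	no
Slc4a3	2.42	0.15	1.97	0.001	larger	yes	no
Slc4a10	1.74	0.28	1.81	0.001	larger	yes	no
Cacna2d3	2.06	0.30	1.72	0.001	larger	no	no
Ahi1	1.73	0.14	1.71	0.001	larger	yes	no
Rasgrf1	1.90	0.12	1.68	0.001	larger	yes	no
Slc1a6	1.83	0.18	1.67	0.001	larger	no	no
Lynx1	1.53	0.13	1.67	0.001	larger	no	no
Cdk5rap2	0.50	0.07	0.68	0.001	larger	yes	no
Stx2	0.40	0.02	0.54	0.001	larger	yes	no
Cpne3	0.30	0.04	0.45	0.001	larger	no	no
Scn9a	0.33	0.07	0.34	0.001	larger	yes	no
Syt2	1.98	0.16	1.48	0.001	smaller	no	no
Actl6b	1.41	0.10	1.47	0.001	smaller	yes	no
Gria3	1.74	0.07	1.40	0.001	smaller	no	no
Syngr3	1.56	0.09	1.30	0.001	smaller	no	yes
Glrb	1.53	0.13	1.29	0.001	smaller	no	yes
Gabbr1	1.33	0.20	1.25	0.001	smaller	no	yes
Plekha5	0.69	0.07	0.77	0.001	smaller	yes	no
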