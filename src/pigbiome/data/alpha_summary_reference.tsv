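index	pre_overall	post_overall	pre_white	pre_oil	pre_traditional	post_white	post_oil	post_traditional	p_treatment	p_weaning
chao1	950.67	1537.03	876.37	955.26	1008.01	1700.61	1444.47	1493.26	0.3052217	1.15e-10
fisher_alpha	124.70	198.60	115.18	118.00	139.34	216.74	190.75	191.34	0.4259763	3.53e-10
observed_otus	717.44	1181.94	658.30	721.92	762.25	1300.00	1091.92	1173.58	0.5885714	5.95e-10
shannon	5.02	6.55	4.36	4.95	5.63	6.74	6.53	6.42	0.0019982	5.55e-09
simpson	0.85	0.97	0.74	0.87	0.91	0.97	0.96	0.97	0.0000131	3.21e-07
equitability	0.53	0.65	0.47	0.52	0.59	0.65	0.65	0.64	0.0012893	6.08e-07
simpson_e	0.02	0.03	0.02	0.02	0.03	0.04	0.03	0.04	0.4187639	3.51e-02
ACE	1477.18	2229.95	1285.03	1506.04	1608.43	2452.06	2124.21	2150.60	0.1367301	3.08e-10
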