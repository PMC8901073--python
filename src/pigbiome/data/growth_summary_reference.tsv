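cohort	group	n	bw_d1	bw_d26	bw_d58	adg_pre	adg_post	deaths_pre	deaths_post	mortality_pre	mortality_post
all	white	57	1.279	6.907	19.992	0.215	0.409	7	1	0.123	0.018
all	traditional	68	1.248	7.444	20.685	0.240	0.412	5	1	0.074	0.015
all	oil	72	1.240	6.944	20.699	0.221	0.428	12	1	0.167	0.014
sequenced	white	5	1.310	5.720	20.342	0.170	0.457	0	0	0.000	0.000
sequenced	traditional	6	1.342	7.392	20.966	0.233	0.424	0	0	0.000	0.000
sequenced	oil	6	1.350	7.333	21.019	0.230	0.428	0	0	0.000	0.000
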