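id	father	mother	sex	is_fetus	alpha_genotype	beta_genotype	reported_genotype	RBC	HGB	MCV	MCH	MCHC	HbA2
I-1	0	0	male	0	HKAA/D37	B41_42/B_N	HKαα/-α3.7	5.41	104	64.9	19.2	296	6.4
I-2	0	0	female	0	SEA/AA	B_N/B_N	--SEA/αα	5.38	118	73.4	21.9	299	2.3
II-1	0	0	female	0	D42/AA	B_N/B_N	-α4.2/αα	4.03	104	79.7	25.8	324	2.6
II-2	I-1	I-2	male	0	HKAA/SEA	B_N/B_N	HKαα/--SEA	6.98	139	64.6	19.9	308	2.5
II-3	I-1	I-2	female	0	HKAA/SEA	B_N/B_N	HKαα/--SEA	5.85	123	70	21	296	2.5
II-4	I-1	I-2	female	0	D37/SEA	B_N/B_N	-α3.7/--SEA	5.38	90	58.6	16.7	286	1.3
II-5	I-1	I-2	male	0	D37/AA	B41_42/B_N	-α3.7/αα	7.12	134	63.3	18.8	297	6.4
II-6	0	0	female	0	AA/AA	B_N/B_N	αα/αα	4.69	145	93.6	30.9	330	2.9
III-1	II-2	II-1	male	0	HKAA/D42	B_N/B_N	HKαα/-α4.2	5.12	126	74.2	24.6	332	2.9
III-2	II-2	II-1	unknown	1	HKAA/D42	B_N/B_N	HKαα/-α4.2	NA	NA	NA	NA	NA	NA
III-3	0	II-3	male	0	HKAA/AA	B_N/B_N	HKαα/?	5.58	133	74.4	23.8	320	3.2
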