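protein	chrom	pos	rsid	cohorts	cis_trans	helic_maf_pct	gnomad_nfe_maf_pct	consequence
SUMF2	7	71973324	rs568788425	MANOLIS	cis	0.80	0.04	intron
CD1C	1	158292108	rs201448758	MANOLIS+Pomak	cis	1.21	0.01	missense
ENO2	12	6862641	rs184861396	MANOLIS+Pomak	cis	0.45	0.20	intron
ITGB7	12	53519700	rs541150953	MANOLIS+Pomak	cis	1.53	0.18	intron
ACP6	1	121470180	rs114127018	Pomak	cis	0.90	0.01	intergenic
APLP1	19	35871901	rs767668877	Pomak	cis	1.00	0.00	missense
CD93	1	3888781	rs912070506	Pomak	trans	0.20	0.01	intergenic
CD93	2	207672303	rs942471010	Pomak	trans	0.40	0.01	intergenic
CD93	2	227266736	rs1396628045	Pomak	trans	0.40	0.01	non_transcript_exon
IGFBP7	4	67658568	rs539585543	Pomak	cis	0.70	0.02	intron
IL1RL2	2	89009162	rs543843028	Pomak	cis	2.00	0.13	intergenic
KYAT1	9	126833282	rs746374838	Pomak	cis	0.60	0.00	missense
MMP2	16	55496937	rs144755357	Pomak	cis	1.30	0.01	missense
PSGL1	12	97893711	rs185338771	Pomak	cis	0.40	0.00	intergenic
VSIG2	11	124706898	rs959226701	Pomak	cis	0.60	0.15	intergenic
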