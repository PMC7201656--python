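# coordinates: 1-based inclusive
locus_id	coordinate	orientation	type	status	subtype	frequency	age_mya	gene_context
solo-1p35.1	Chr1: 33529117-33530085	(+)	solo_LTR	novel_reference	LTR5_Hs	.	.	.
solo-3p12.3	Chr3: 75586870-75587898	(+)	solo_LTR	novel_reference	LTR5A	.	.	1.3 kb upstream of CTD-2023G6.3
solo-3q21.2	Chr3: 125518094-125519118	(-)	solo_LTR	novel_reference	LTR5A	.	.	1.3 kb downstream of LOC105374312
solo-4p16.3	Chr4: 4076017-4077040	(+)	solo_LTR	novel_reference	LTR5A	.	.	BC042823 (exon5/5)
solo-4p16.1a	Chr4: 9036143-9037177	(-)	solo_LTR	novel_reference	LTR5A	.	.	.
solo-4p16.1b	Chr4: 9568938-9569963	(-)	solo_LTR	novel_reference	LTR5A	.	.	AF073924 (intron 13/41)
solo-6p22.2	Chr6: 25999459-26000425	(+)	solo_LTR	novel_reference	LTR5_Hs	.	.	U91328.19 (exon 2/2)
solo-7p14.3	Chr7: 30758200-30759205	(-)	solo_LTR	novel_reference	LTR5B	.	.	INMT (intron 1/3)
solo-8p23.1a	Chr8: 12481601-12482613	(+)	solo_LTR	novel_reference	LTR5A	.	.	LOC729732 (intron 2/5)
solo-8p23.1b	Chr8: 6984509-6985529	(-)	solo_LTR	novel_reference	LTR5A	.	.	.
solo-8p23.1c	Chr8: 7957620-7958646	(-)	solo_LTR	novel_reference	LTR5A	.	.	FAM85B (exon 4/4)
solo-8p12	Chr8: 29976041-29976903	(-)	solo_LTR	novel_reference	LTR5B	.	.	LEPROTL1 transcript variant 2 (intron3/3)
solo-10q24.1	Chr10: 99176602-99177875	(-)	solo_LTR	novel_reference	LTR5_Hs	.	.	0.6 kb upstream of LOC644215, with Alu int
solo-11q12.2	Chr11: 60480658-60481952	(-)	solo_LTR	novel_reference	LTR5_Hs	.	.	MS4A8 (intron5/6), with Alu int
solo-11p15.4a	Chr11: 3566582-3567605	(+)	solo_LTR	novel_reference	LTR5A	.	.	LOC101927708 (intron1/2)
solo-11p15.4b	Chr11: 4481698-4482706	(-)	solo_LTR	novel_reference	LTR5B	.	.	.
solo-12q23.3	Chr12: 108220231-108221198	(-)	solo_LTR	novel_reference	LTR5_Hs	.	.	KJ893228 (coding PRDM4) (intron 4/13)
solo-16q23.1	Chr16: 75848903-75850194	(-)	solo_LTR	novel_reference	LTR5_Hs	.	.	with Alu int
solo-19q13.41	Chr19: 53435868-53437508	(-)	solo_LTR	novel_reference	LTR5B	.	.	ZNF321P (intron1/1), with Alu int
solo-19p12	Chr19: 23459830-23461346	(-)	solo_LTR	novel_reference	LTR5B	.	.	with LTR6A int
solo-20p11.21a	Chr20: 23736917-23737884	(-)	solo_LTR	novel_reference	LTR5_Hs	.	.	.
solo-20p11.21b	Chr20: 23674997-23675964	(-)	solo_LTR	novel_reference	LTR5_Hs	.	.	.
solo-Yq11.223	ChrY: 26026513-26027237	(-)	solo_LTR	novel_reference	LTR5_Hs	.	.	.
solo-Yq11.23	ChrY: 27935164-27935888	(+)	solo_LTR	novel_reference	LTR5_Hs	.	.	.
solo-Un212	Un_gl000212: 79707-80671	(+)	solo_LTR	novel_reference	LTR5_Hs	.	.	.
solo-Un219	Un_gl000219: 31165-32127	(-)	solo_LTR	novel_reference	LTR5_Hs	.	.	.
solo-Un222	Un_gl000222: 107341-108304	(-)	solo_LTR	novel_reference	LTR5_Hs	.	.	.
solo-Un231	Un_gl000231: 22479-23506	(+)	solo_LTR	novel_reference	LTR5A	.	.	.
solo-Un232a	Un_gl000232: 2327-3289	(+)	solo_LTR	novel_reference	LTR5_Hs	.	.	.
solo-Un232b	Un_gl000232: 8571-9521	(-)	solo_LTR	novel_reference	LTR5_Hs	.	.	.
N3q22.1	Chr3: 130166557-130166563	(+)	solo_LTR	novel_non_reference	unknown	.	.	HERVK11-int, COL6A5 (intron 36/41)
N6p21.32	Chr6: 32643459-32643464	(+)	solo_LTR	novel_non_reference	LTR5_Hs	.	.	L1PA10
N15q21.2	Chr15: 51650823-51650829	(+)	solo_LTR	novel_non_reference	unknown	.	.	HERV17-int, GLDN (intron 1/9)
N19q11	Chr19: 28198583-28198588	(+)	solo_LTR	novel_non_reference	unknown	.	.	inserted into HERV17-int
N21q22.11	Chr21: 33824215-33824220	(-)	solo_LTR	novel_non_reference	unknown	.	.	MLT1C, EVA1c (intron 1/7)
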