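rsid	chrom	pos_mb	score_primary	pct_primary	score_secondary	pct_secondary	pp_plt	nearest_gene	eqtl_genes	gata_overlap	in_ld_block
rs11240368	1	205.1	1.12	97	0.52	95		DSTYK	CNTN2,TMEM81	yes	yes
rs3771535	2	70.0	0.94	95	0.53	95	0.01	ANXA4	GMCL1,SNRNP27	yes	yes
rs10180681	2	121.0	1.41	98	0.63	97	0.01	RALB	EPB41L5,PTPN4,RALB	yes	yes
rs10180682	2	121.0	1.41	98	0.64	97	0.01	RALB	EPB41L5,PTPN4,RALB	yes	yes
rs9646785	2	172.0	1.27	98	0.58	96		TLK1	GAD1,GORASP2	yes	yes
rs6771578	3	167.4	1.14	97	0.60	96	0.003	PDCD10	PDCD10,SERPINI1,WDR49	yes	yes
rs12652692	5	77.8	3.62	99	0.57	96	0.01	LHFPL2	LHFPL2,SCAMP1	yes	yes
rs72793280	5	131.6	2.73	99	0.89	99	0.001	P4HA2	ACSL6,P4HA2,PDLIM4,SLC22A4,SLC22A5	yes	yes
rs1741820	6	122.8	1.75	99	0.55	96		HSF2	HSF2,PKIB	yes	yes
rs342293	7	106.4	1.80	99	0.94	99	0.99	CCDC71L	PIK3CG	yes	yes
rs1326599	8	56.7	1.75	99	0.60	96		TMEM68	LYN,TGS,TMEM68	yes	yes
rs9704108	11	0.3	1.12	97	0.85	99	0.087	IFITM2	IFITM2	yes	yes
rs11071720	15	63.3	1.53	98	0.58	96	0.98	TPM1	APH1B,LACTB,RAB8B,TPM1	yes	yes
rs231651	17	2.0	0.92	95	0.54	95	0.005	EST1A	DPH1,SMG6,SRR	yes	yes
rs1654439	19	55.6	2.69	99	0.58	96	0.002	RDH13	GP6,NLRP2,RDH13	yes	yes
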