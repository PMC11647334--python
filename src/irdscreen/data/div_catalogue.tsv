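gene	transcript	cdna_name	protein	rsid	mechanism	lovd_entries	sa_probands	locus
ABCA4	NM_000350.3	c.769-784C>T	p.[=,Leu257Aspfs*3]	rs144695319	pseudoexon_inclusion	8	1	ABCA4:c.769-784C>T
ABCA4	NM_000350.3	c.859-640A>G	p.Phe287Tyrfs*69	.	pseudoexon_inclusion	0	2	ABCA4:c.859-640A>G
ABCA4	NM_000350.3	c.4253+43G>A	p.[=,Ile1377Hisfs*3]	rs61754045	exon_skipping	58	1	ABCA4:c.4253+43G>A
ABCA4	NM_000350.3	c.4539+2001G>A	p.[=,Arg1514Leufs*36]	rs1457937638	pseudoexon_inclusion	41	24	ABCA4:c.4539+2001G>A
ABCA4	NM_000350.3	c.5196+1056A>G	p.Met1733Valfs*2	rs886044749	pseudoexon_inclusion	8	1	ABCA4:c.5196+1056A>G
CEP290	NM_025114.4	c.2991+1655A>G	p.Cys998*	rs281865192	pseudoexon_inclusion	8	2	CEP290:c.2991+1655A>G
USH2A	NM_206933.4	c.7595-2144A>G	p.Lys2532Thrfs*56	rs786200928	pseudoexon_inclusion	39	0	USH2A:c.7595-2144A>G
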