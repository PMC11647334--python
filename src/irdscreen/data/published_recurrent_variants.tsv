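gene	transcript	cdna	protein	rsid	n_indigenous_african	n_caucasian	n_mixed_ancestry
ABCA4	NM_000350.3	c.1804C>T	p.Arg602Trp	rs61749409	0	4	1
ABCA4	NM_000350.3	c.4634+1delG	p.(?)	.	5	0	0
ABCA4	NM_000350.3	c.454C>T	p.(Arg152*)	rs62646861	0	2	1
ABCA4	NM_000350.3	c.4469G>A	p.Cys1490Tyr	rs61751402	0	2	0
ABCA4	NM_000350.3	c.5603A>T	p.Asn1868Ile	rs1801466	0	3	0
ABCA4	NM_000350.3	c.4539+2001G>A	p.[=,Arg1514Leufs*36]	rs1457937638	0	2	0
ABCA4	NM_000350.3	c.6320G>A	p.Arg2107His	rs62642564	2	0	0
ABCA4	NM_000350.3	c.6617T>A	p.(Leu2206His)	.	2	0	0
CEP290	NM_025114.4	c.4723A>T	p.Lys1575*	rs137852834	0	1	1
CERKL	NM_201548.5	c.365T>G	p.(Leu122Arg)	rs558913945	2	0	0
CRB1	NM_201253.3	c.2234C>T	p.(Thr745Met)	rs28939720	2	0	1
EYS	NM_001142800.2	c.3443+1G>T	p.(?)	rs373441420	2	0	0
MYO7A	NM_000260.4	c.6377delC	p.(Pro2126Leufs*5)	.	2	0	0
PRCD	NM_001077620.3	c.2T>C	p.(Met1?)	rs527236092	2	0	0
RHO	NM_000539.3	c.541G>A	p.Glu181Lys	rs775557680	1	1	0
USH2A	NM_206933.4	c.949C>A	p.=	rs111033272	0	3	0
USH2A	NM_206933.4	c.7595-2144A>G	p.Phe287Tyrfs*69	rs786200928	0	2	0
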