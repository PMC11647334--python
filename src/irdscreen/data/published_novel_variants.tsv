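coordinates	gene	transcript	exon	cdna	protein	function	n_probands
chr1:94548906	ABCA4	NM_000350.3	7	c.858+2T>C	p.(?)	Splice	1
chr1:94463529	ABCA4	NM_000350.3	48	c.6617T>A	p.(Leu2206His)	Missense	2
chr5:90041526	ADGRV1	NM_032119.4	52	c.10888G>T	p.(Gly3630*)	Nonsense	1
chr5:89969877	ADGRV1	NM_032119.4	23	c.4937_4938insCA	p.(Val1649Metfs*16)	Frameshift insertion	1
chr11:61723315	BEST1	NM_001139443.2	3	c.193C>G	p.(Arg65Gly)	Missense	1
chr12:88457876	CEP290	NM_025114.4	45	c.6152C>G	p.(Ser2051*)	Nonsense	1
chr1:197297897	CRB1	NM_201253.3	2	c.416G>T	p.(Gly139Val)	Missense	1
chr17:7907173	GUCY2D	NM_000180.4	3	c.725T>A	p.(Val242Glu)	Missense	1
chr17:7919272	GUCY2D	NM_000180.4	17	c.3071C>T	p.(Thr1024Ile)	Missense	1
chr7:128038667	IMPDH1	NM_000883.4	10	c.875G>T	p.(Gly292Val)	Splice	1
chr11:76858884	MYO7A	NM_000260.4	4	c.174dup	p.(Met59Tyrfs*81)	Frameshift insertion	1
chr2:29293666	PCARE	NM_001029883.3	1	c.3461delG	p.(Gly1154Alafs*18)	Frameshift deletion	1
chr3:129252546	RHO	NM_000539.3	5	c.1032G>T	p.(Gln344His)	Missense	1
chrX:18660183	RS1	NM_000330.4	6	c.616T>G	p.(Trp206Gly)	Missense	1
chr1:216420560	USH2A	NM_206933.4	13	c.2176T>G	p.(Cys726Gly)	Missense	1
chr1:215848834	USH2A	NM_206933.4	63	c.12419G>C	p.(Cys4140Ser)	Missense	1
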