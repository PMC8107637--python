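family	gc_id	n_affected	hgvs_c	hgvs_p	consequence	segregation	gnomad_af	domain
family_1	GC21294	1	c.577C>T	p.(Arg193Cys)	missense	Paternal DNA unavailable; Maternal: p.(Arg193Cys)	0.000006573	FAD/NAD(P) BD
family_1	GC21294	1	c.1115C>A	p.(Pro372His)	missense	Paternal DNA unavailable; Maternal: p.(Arg193Cys)	0.00001315	FAD/NAD(P) BD
family_2	GC17577	2	c.925C>T	p.(Arg309*)	stop_gain	Paternal: p.(Arg309*)	0.00002628	FAD/NAD(P) BD
family_2	GC17577	2	c.1115C>A	p.(Pro372His)	missense	Maternal: p.(Pro372His)	0.00001315	FAD/NAD(P) BD
family_3	GC15689	1	c.461C>T	p.(Ala154Val)	missense	Paternal DNA unavailable; Maternal: p.(Arg275Trp)	0	FAD/NAD(P) BD
family_3	GC15689	1	c.823C>T	p.(Arg275Trp)	missense	Paternal DNA unavailable; Maternal: p.(Arg275Trp)	0	FAD/NAD(P) BD
family_4		1	c.1115C>A	p.(Pro372His)	missense	Maternal DNA unavailable	0.00001315	FAD/NAD(P) BD
family_4		1	c.1279G>C	p.(Ala427Pro)	missense	Paternal: p.(Ala427Pro)	0	NAD(P) BD
family_5	GC28630	1	c.614C>T	p.(Thr205Met)	missense	Sibling II:2: p.(Thr205Met); siblings II:1 and II:3 carry no variant	0.00001314	FAD/NAD(P) BD
family_5	GC28630	1	c.823C>T	p.(Arg275Trp)	missense	Sibling II:2: p.(Thr205Met); siblings II:1 and II:3 carry no variant	0	FAD/NAD(P) BD
family_6	GC28579	1	c.1115C>A	p.(Pro372His)	missense	No other DNA available	0.00001315	FAD/NAD(P) BD
family_6	GC28579	1	chr17:74818633-74888183del		whole_gene_deletion	No other DNA available
family_7	GC28550	2	c.1115C>A	p.(Pro372His)	missense	Paternal DNA unavailable	0.00001315	FAD/NAD(P) BD
family_7	GC28550	2	c.1189G>A	p.(Gly397Ser)	missense	Maternal: p.(Gly397Ser)	0.00003285	NAD(P) BD
family_8		1	c.724C>T	p.(Arg242Trp)	missense	No other DNA available	0.000006573	FAD/NAD(P) BD
family_8		1	c.916C>T	p.(Arg306Cys)	missense	No other DNA available	0.00004600	FAD/NAD(P) BD
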