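gene_id	symbol	r	p
ENSMUSG00000086425	Gdal1	1.000	0.00
ENSMUSG00000052435	Cebpe	0.991	1.12e-4
ENSMUSG00000020160	Meis1	-0.991	1.22e-4
ENSMUSG00000005583	Mef2c	-0.964	1.96e-3
ENSMUSG00000044220	Nkx2-3	-0.962	2.13e-3
ENSMUSG00000076431	Sox4	-0.961	2.26e-3
ENSMUSG00000038236	Hoxa7	-0.953	3.29e-3
ENSMUSG00000055148	Klf2	0.947	4.08e-3
ENSMUSG00000022508	Bcl6	0.946	4.37e-3
ENSMUSG00000038227	Hoxa9	-0.941	5.17e-3
ENSMUSG00000034957	Cebpa	0.939	5.39e-3
ENSMUSG00000021025	Nfkbia	0.935	6.15e-3
ENSMUSG00000021356	Irf4	0.933	6.62e-3
ENSMUSG00000038253	Hoxa5	-0.896	1.55e-2
ENSMUSG00000041515	Irf8	-0.875	2.25e-2
ENSMUSG00000020644	Id2	0.814	4.87e-2
ENSMUSG00000037465	Klf10	0.784	6.48e-2
ENSMUSG00000015053	Gata2	0.645	1.66e-1
ENSMUSG00000052684	Jun	0.507	3.05e-1
ENSMUSG00000022528	Hes1	0.293	5.73e-1
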