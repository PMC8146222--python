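gene_id	symbol	chromosome	scaled_degree	enriched_in	adj_p
ENSMUSG00000118061	Rbfaos	chr18	0.771	diff_arrest	8.45e-13
ENSMUSG00000104184	Gm37818	chr11	0.833	diff_arrest	1.17e-11
ENSMUSG00000086425	Gdal1	chr2	0.754	normal_diff	1.73e-8
ENSMUSG00000084085	Gm16140	chr11	0.751	diff_arrest	2.77e-5
ENSMUSG00000109799	Gm45515	chr7	0.821	diff_arrest	4.23e-5
ENSMUSG00000027196	Alkbh3os1	chr2	0.834	diff_arrest	6.86e-5
ENSMUSG00000087026	A230103J11Rik	chr8	0.772	diff_arrest	3.00e-4
ENSMUSG00000097057	Gm17638	chr15	0.844	diff_arrest	5.28e-4
ENSMUSG00000107320	Gm42549	chr6	0.780	diff_arrest	4.61e-3
ENSMUSG00000107480	Gm44165	chr7	0.757	normal_diff	8.90e-3
ENSMUSG00000113184	Gm49654	chr12	0.836	normal_diff	1.75e-2
ENSMUSG00000108402	9430064I24Rik	chr7	0.817	diff_arrest	2.28e-2
ENSMUSG00000078308	Gm47854	chr9	0.905	normal_diff	3.85e-2
ENSMUSG00000097772	5430416N02Rik	chr5	0.960	diff_arrest	3.85e-2
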