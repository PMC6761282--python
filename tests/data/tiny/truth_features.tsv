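feature	kind	direction	true_logfc	coupled
mir-0005	miRNA	1	2	False
mir-0009	miRNA	1	2	False
mir-0019	miRNA	-1	-2	False
mir-0021	miRNA	-1	-2	False
mir-0040	miRNA	1	2	False
mir-0048	miRNA	1	2	False
GENE00090	gene	-1	-2	False
GENE00091	gene	1	2	False
GENE00101	gene	-1	-2	False
GENE00131	gene	1	2	False
GENE00138	gene	1	2	False
GENE00159	gene	-1	-2	False
GENE00239	gene	1	2	False
GENE00241	gene	1	2	False
GENE00249	gene	-1	-2	False
GENE00256	gene	1	2	False
GENE00278	gene	1	2	False
GENE00304	gene	1	2	False
GENE00352	gene	-1	-2	False
GENE00359	gene	-1	-2	False
GENE00363	gene	1	2	False
GENE00365	gene	-1	-2	False
GENE00370	gene	1	2	False
GENE00431	gene	1	2	False
GENE00446	gene	-1	-2	False
GENE00482	gene	-1	-2	False
GENE00118	gene	-1	-1.6	True
GENE00163	gene	-1	-1.6	True
GENE00194	gene	-1	-1.6	True
GENE00315	gene	-1	-1.6	True
GENE00368	gene	-1	-1.6	True
GENE00387	gene	-1	-1.6	True
GENE00428	gene	-1	-1.6	True
GENE00478	gene	-1	-1.6	True
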