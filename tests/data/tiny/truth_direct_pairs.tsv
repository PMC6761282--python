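mirna	gene
mir-0005	GENE00315
mir-0005	GENE00368
mir-0005	GENE00428
mir-0009	GENE00194
mir-0009	GENE00478
mir-0040	GENE00118
mir-0040	GENE00163
mir-0040	GENE00387
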