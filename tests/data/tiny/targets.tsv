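mirna	gene	source	evidence
mir-0005	GENE00315	sim	predicted
mir-0005	GENE00368	sim	predicted
mir-0005	GENE00428	sim	predicted
mir-0009	GENE00194	sim	predicted
mir-0009	GENE00478	sim	predicted
mir-0040	GENE00118	sim	predicted
mir-0040	GENE00163	sim	predicted
mir-0040	GENE00387	sim	predicted
mir-0005	GENE00067	sim	predicted
mir-0005	GENE00079	sim	predicted
mir-0005	GENE00097	sim	predicted
mir-0005	GENE00135	sim	predicted
mir-0005	GENE00137	sim	predicted
mir-0005	GENE00139	sim	predicted
mir-0005	GENE00145	sim	predicted
mir-0005	GENE00180	sim	predicted
mir-0005	GENE00183	sim	predicted
mir-0005	GENE00278	sim	predicted
mir-0005	GENE00294	sim	predicted
mir-0005	GENE00321	sim	predicted
mir-0005	GENE00394	sim	predicted
mir-0005	GENE00426	sim	predicted
mir-0005	GENE00439	sim	predicted
mir-0005	GENE00487	sim	predicted
mir-0005	GENE00496	sim	predicted
mir-0005	GENE00500	sim	predicted
mir-0009	GENE00069	sim	predicted
mir-0009	GENE00077	sim	predicted
mir-0009	GENE00084	sim	predicted
mir-0009	GENE00135	sim	predicted
mir-0009	GENE00137	sim	predicted
mir-0009	GENE00258	sim	predicted
mir-0009	GENE00269	sim	predicted
mir-0009	GENE00296	sim	predicted
mir-0009	GENE00307	sim	predicted
mir-0009	GENE00309	sim	predicted
mir-0009	GENE00374	sim	predicted
mir-0009	GENE00383	sim	predicted
mir-0009	GENE00384	sim	predicted
mir-0019	GENE00053	sim	predicted
mir-0019	GENE00129	sim	predicted
mir-0019	GENE00173	sim	predicted
mir-0019	GENE00181	sim	predicted
mir-0019	GENE00245	sim	predicted
mir-0019	GENE00260	sim	predicted
mir-0019	GENE00275	sim	predicted
mir-0019	GENE00293	sim	predicted
mir-0019	GENE00299	sim	predicted
mir-0019	GENE00317	sim	predicted
mir-0019	GENE00374	sim	predicted
mir-0019	GENE00377	sim	predicted
mir-0019	GENE00437	sim	predicted
mir-0019	GENE00467	sim	predicted
mir-0021	GENE00017	sim	predicted
mir-0021	GENE00081	sim	predicted
mir-0021	GENE00120	sim	predicted
mir-0021	GENE00180	sim	predicted
mir-0021	GENE00201	sim	predicted
mir-0021	GENE00264	sim	predicted
mir-0021	GENE00351	sim	predicted
mir-0021	GENE00374	sim	predicted
mir-0021	GENE00380	sim	predicted
mir-0021	GENE00453	sim	predicted
mir-0021	GENE00480	sim	predicted
mir-0040	GENE00026	sim	predicted
mir-0040	GENE00047	sim	predicted
mir-0040	GENE00059	sim	predicted
mir-0040	GENE00158	sim	predicted
mir-0040	GENE00189	sim	predicted
mir-0040	GENE00205	sim	predicted
mir-0040	GENE00237	sim	predicted
mir-0040	GENE00299	sim	predicted
mir-0040	GENE00340	sim	predicted
mir-0040	GENE00374	sim	predicted
mir-0040	GENE00383	sim	predicted
mir-0040	GENE00422	sim	predicted
mir-0040	GENE00424	sim	predicted
mir-0040	GENE00435	sim	predicted
mir-0040	GENE00442	sim	predicted
mir-0040	GENE00451	sim	predicted
mir-0048	GENE00097	sim	predicted
mir-0048	GENE00110	sim	predicted
mir-0048	GENE00165	sim	predicted
mir-0048	GENE00176	sim	predicted
mir-0048	GENE00309	sim	predicted
mir-0048	GENE00379	sim	predicted
mir-0048	GENE00412	sim	predicted
mir-0048	GENE00450	sim	predicted
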