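AGING_SET	synthetic set enriched in planted age-associated genes	GENE00017	GENE00023	GENE00053	GENE00059	GENE00063	GENE00090	GENE00131	GENE00159	GENE00163	GENE00194	GENE00227	GENE00235	GENE00241	GENE00256	GENE00258	GENE00278	GENE00287	GENE00289	GENE00304	GENE00315	GENE00342	GENE00352	GENE00359	GENE00363	GENE00365	GENE00368	GENE00370	GENE00379	GENE00400	GENE00428	GENE00429	GENE00431	GENE00446	GENE00458	GENE00459	GENE00462	GENE00478	GENE00482	GENE00490	GENE00499
RANDOM_SET_01	synthetic random gene set	GENE00002	GENE00003	GENE00035	GENE00040	GENE00044	GENE00063	GENE00075	GENE00085	GENE00101	GENE00118	GENE00124	GENE00139	GENE00153	GENE00155	GENE00156	GENE00186	GENE00188	GENE00193	GENE00194	GENE00207	GENE00226	GENE00249	GENE00257	GENE00260	GENE00275	GENE00276	GENE00286	GENE00299	GENE00312	GENE00315	GENE00316	GENE00326	GENE00345	GENE00382	GENE00401	GENE00407	GENE00417	GENE00426	GENE00434	GENE00482
RANDOM_SET_02	synthetic random gene set	GENE00077	GENE00107	GENE00110	GENE00135	GENE00139	GENE00141	GENE00142	GENE00175	GENE00178	GENE00186	GENE00187	GENE00228	GENE00232	GENE00239	GENE00243	GENE00256	GENE00260	GENE00277	GENE00288	GENE00303	GENE00313	GENE00316	GENE00322	GENE00335	GENE00338	GENE00345	GENE00347	GENE00379	GENE00391	GENE00408	GENE00413	GENE00414	GENE00443	GENE00449	GENE00450	GENE00465	GENE00474	GENE00481	GENE00487	GENE00492
RANDOM_SET_03	synthetic random gene set	GENE00005	GENE00019	GENE00020	GENE00032	GENE00043	GENE00045	GENE00050	GENE00072	GENE00082	GENE00090	GENE00128	GENE00133	GENE00151	GENE00199	GENE00210	GENE00213	GENE00231	GENE00236	GENE00244	GENE00246	GENE00248	GENE00257	GENE00260	GENE00271	GENE00280	GENE00283	GENE00319	GENE00322	GENE00356	GENE00387	GENE00422	GENE00425	GENE00427	GENE00437	GENE00442	GENE00443	GENE00454	GENE00468	GENE00475	GENE00488
RANDOM_SET_04	synthetic random gene set	GENE00005	GENE00041	GENE00044	GENE00058	GENE00081	GENE00082	GENE00085	GENE00087	GENE00098	GENE00105	GENE00107	GENE00108	GENE00115	GENE00124	GENE00137	GENE00157	GENE00159	GENE00161	GENE00162	GENE00186	GENE00192	GENE00206	GENE00212	GENE00297	GENE00320	GENE00342	GENE00347	GENE00360	GENE00368	GENE00383	GENE00388	GENE00389	GENE00393	GENE00404	GENE00412	GENE00438	GENE00448	GENE00457	GENE00466	GENE00473
RANDOM_SET_05	synthetic random gene set	GENE00002	GENE00004	GENE00023	GENE00035	GENE00038	GENE00048	GENE00050	GENE00064	GENE00074	GENE00078	GENE00125	GENE00133	GENE00135	GENE00164	GENE00191	GENE00215	GENE00216	GENE00217	GENE00233	GENE00244	GENE00260	GENE00288	GENE00290	GENE00297	GENE00319	GENE00323	GENE00328	GENE00329	GENE00338	GENE00343	GENE00345	GENE00355	GENE00368	GENE00369	GENE00393	GENE00407	GENE00424	GENE00465	GENE00478	GENE00486
RANDOM_SET_06	synthetic random gene set	GENE00005	GENE00010	GENE00017	GENE00023	GENE00028	GENE00034	GENE00037	GENE00100	GENE00130	GENE00157	GENE00163	GENE00167	GENE00170	GENE00195	GENE00196	GENE00224	GENE00232	GENE00247	GENE00251	GENE00252	GENE00260	GENE00261	GENE00266	GENE00298	GENE00304	GENE00315	GENE00370	GENE00389	GENE00397	GENE00404	GENE00414	GENE00418	GENE00426	GENE00428	GENE00449	GENE00459	GENE00465	GENE00471	GENE00487	GENE00498
RANDOM_SET_07	synthetic random gene set	GENE00016	GENE00019	GENE00022	GENE00029	GENE00044	GENE00045	GENE00056	GENE00059	GENE00074	GENE00089	GENE00119	GENE00135	GENE00138	GENE00140	GENE00157	GENE00159	GENE00177	GENE00185	GENE00195	GENE00240	GENE00244	GENE00253	GENE00268	GENE00270	GENE00284	GENE00295	GENE00300	GENE00309	GENE00311	GENE00333	GENE00343	GENE00366	GENE00369	GENE00380	GENE00384	GENE00422	GENE00432	GENE00433	GENE00456	GENE00478
RANDOM_SET_08	synthetic random gene set	GENE00007	GENE00036	GENE00048	GENE00050	GENE00059	GENE00064	GENE00068	GENE00076	GENE00078	GENE00080	GENE00101	GENE00112	GENE00114	GENE00115	GENE00125	GENE00156	GENE00176	GENE00206	GENE00220	GENE00226	GENE00238	GENE00253	GENE00257	GENE00267	GENE00271	GENE00276	GENE00283	GENE00295	GENE00309	GENE00337	GENE00352	GENE00357	GENE00369	GENE00402	GENE00403	GENE00429	GENE00438	GENE00444	GENE00467	GENE00481
RANDOM_SET_09	synthetic random gene set	GENE00001	GENE00021	GENE00033	GENE00045	GENE00057	GENE00084	GENE00091	GENE00095	GENE00107	GENE00108	GENE00147	GENE00148	GENE00164	GENE00175	GENE00181	GENE00190	GENE00223	GENE00277	GENE00286	GENE00293	GENE00304	GENE00313	GENE00318	GENE00335	GENE00337	GENE00340	GENE00357	GENE00363	GENE00366	GENE00369	GENE00372	GENE00381	GENE00402	GENE00407	GENE00409	GENE00417	GENE00427	GENE00439	GENE00456	GENE00458
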