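# Per-organism genome size, array count and gene-set counts by source
# for the 17-bacteria Affymetrix compendium the consistency study surveyed.
organism	n_genes	n_arrays	go_bp	go_cc	go_mf	kegg	operon	seed_ss	seed_scenario	seed_path	n_sets
Streptomyces coelicolor A3(2)	7989	55	799	117	819	113	1626	200	139	158	3971
Bacteroides thetaiotaomicron VPI-5482	4778	41	695	84	615	79	1008	193	93	98	2865
Synechococcus elongatus PCC 7942	1849	104	651	106	564	89	295	257	72	90	2124
Thermus thermophilus	2215	407	604	79	499	83	441	180	86	92	2064
Staphylococcus aureus subsp. aureus Mu50	2750	852	697	86	604	90	521	360	98	118	2574
Streptococcus agalactiae	1880	78	571	65	477	79	257	238	64	70	1830
Streptococcus pyogenes	1849	89	556	70	488	81	248	256	57	73	1829
Mycoplasma pneumoniae M129	731	43	332	46	252	42	80	80	14	14	860
Bradyrhizobium japonicum	8198	195	457	111	547	103	1672	421	138	156	3605
Rhodobacter sphaeroides	4084	119	767	150	724	103	757	367	110	128	3106
Rickettsia rickettsii str. Iowa	1242	100	445	64	367	59	251	135	14	15	1350
Helicobacter pylori HPAG1	1521	56	572	76	426	77	248	174	42	42	1657
Escherichia coli K12	4329	907	847	115	788	98	752	399	160	169	3328
Pasteurella multocida subsp. multocida str. Pm70	2001	72	653	77	673	81	365	328	88	91	2356
Pseudomonas aeruginosa PA01	5598	176	823	133	835	104	1042	389	136	154	3616
Shewanella oneidensis MR-1	4050	245	746	112	641	95	705	328	109	125	2861
Vibrio parahaemolyticus RIMD 2210633	4515	42	719	109	602	93	920	418	144	165	3170
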