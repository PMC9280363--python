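est_id	clone_id	precursor_start	precursor_stop	known_mature	predicted_mature	family	homolog_id
EG990325.1	GLE089_F01_003	554	644	UGACAGAAGAAAGAGAGCAC	UGAGAGAAGAAAGAGAGGAA	miR156	ath-miR156h
EG980529.1	GLL073_G12_042	382	429	UCGCUUGGGCAGAUCGGGAC	UCGCUUGGUCAGAUCUGCGC	miR168	sof-miR168b
EG984942.1	GLE040_D12_045	201	258	GAGCCAAGGAUGACUUGCCGU	GAGCCAAGGGUGACUUAAUGU	miR169	vvi-miR169l
EG985097.1	GLE041_H10_033	324	379	AGAAUCUUGAUGAUGCUGCAU	AGAAUCUUGAUCAUCCUGUGU	miR172	gma-miR172b
EG987334.1	GLE062_E02_004	369	420	UCCAAAGGGAUCGCAUUGAUC	UCCAAAGGGAUCGCAUGUCAC	miR393	gma-miR393
EG978583.1	GLL055_H01_001	205	253	UUCCACAGCUUUCUUGAACUU	UUUCACAGCUUUCUUGAUUGU	miR396	osa-miR396c
EG975619.1	GLL029_A09_040	413	460	UCAUUGAGUGCAGCGUUGACG	UCUCUGAAUGCAGCGUUGACU	miR397	pab-miR397
EG990966.1	GLE094_G01_002	207	248	UGCCAAAGGAGAAUUGCCC	AUCCAAAGGUGAAUUGCUC	miR399	tae-miR399
EG985485.1	GLE045_G03_010	317	428	UCAUCCUCAUCAUCAUCGUCC	UUAUCAUCAUCCUCAUCAUCC	miR414	osa-miR414
EG978745.1	GLL057_D04_013	137	199	AAAGUUAGAGAAGUUUGACUU	AUAGCUAGAGAAGUUUGAAAU	miR437	osa-miR437
EG976745.1	GLL038_H10_033	311	357	UGCAGUUGCUGCCUCAAGCUU	UUCAUUUGAAGCCUCAAGCUU	miR444	osa-miR444a.2
EG978435.1	GLL054_D09_037	223	300	UUGAGGUGUUUCUACAGGCUA	UUGAGGAGUUUCUACAUUCAA	miR537	ppt-miR537a
EG989794.1	GLE084_D07_029	632	672	UUUGCUUCCAGCUUUUGUCUC	UUUGCUUCCAGCUUUGGUUUG	miR773	ath-miR773
EG985501.1	GLE045_H05_017	388	541	UUGUAGUGCAUAUUUGUUUU	UUGUUAUGCAUGUUGGUUUU	miR1044	ppt-miR1044
EG989165.1	GLE017_B06_023	380	512	UAGUGGGAGAUUUUGUGUAAC	UAUUGGGAAAUUUUGUGUCGC	miR1109	smo-miR1109
EG974827.1	GLL020_C10_038	335	369	CAUUAUGGAACGGAAGGAG	CAUUAUGGAAAGGAAGGGA	miR1132	tae-miR1132
EG986974.1	GLE05_A06_024	36	91	CAACAACAACAAGAAGAAGAAGAU	GAACAAGAAGAAGAAGAAGAAGAA	miR1134	tae-miR1134
EG975778.1	GLL02_E10_036	44	89	GGGGUGUGAUGAUUUGAAAC	UGGGUGUGAGGAUUUGAGAC	miR1167	cre-miR1167
EG989769.1	GLE084_B06_023	158	251	UACCACUGAAAUUAUUGUUCG	UUCAAUUGAAAUUAUUGGUCG	miR1313	pta-miR1313
EG989141.1	GLE079_A10_040	161	752	UUUUGGAACGGAGUGAGUAUU	UUAUGAAACGGAGUGAGUAAU	miR1439	osa-miR1439
EG981106.1	GLL079_F10_035	51	96	UAACUCAACCUUACAAAACC	GAACUCAAGCUAACAAAACC	miR1527	gma-miR1527
EG975750.1	GLL02_C09_038	453	529	AUAAUAAAAAUAAUAAUGA	UUAAUAAAAAUUAUAAAAA	miR1533	gma-miR1533
EG981151.1	GLL010_F06_019	47	191	CUUGUUUGUGGUGAUGUCU	CUGGUCUGUGGUGCUGUCC	miR1535	gma-miR1535
EG983098.1	GLL01_H03_009	96	177	AUAUGGAUUCAGAAUGCAGGU	AUAAGGAAACAGAAUGCAGGA	miR1852	osa-miR1852
EG975952.1	GLL031_C04_014	116	160	UGGUUUUUUUGGAGCAUGAGG	GGAAUUUUUUGGAGCAGGAGG	miR1857	osa-miR1857
EG990914.1	GLE094_C01_006	644	700	UGUGUGUUCCGCUUCUUCUUU	AGCGUCUUCUGCUUCUUCUUU	miR2082	ppt-miR2082
EG983237.1	GLE021_H04_009	192	278	CGGUUUGUCAAGCGGAGUGC	UGCUUUGUCAAGGGGAGUGU	miR2098	osa-miR2098
EG978398.1	GLL054_A10_040	393	497	UUGUGAUGUGAAUGAUUCAU	GGGUGAUGUGAUUGAUUCCU	miR2105	osa-miR2105
EG987207.1	GLE061_C06_022	253	317	AGGAUUAGAGGGACUUGAACC	ACGCUUCGAGGGACUUGAAUC	miR2275	zma-miR2275c
EG986569.1	GLE055_B02_007	573	612	UACAAUUCCUUAGGUGCUUUU	UUCAGCUCCUUAGGUGCAUUU	miR2606	mtr-miR2606a
EG980814.1	GLL076_F12_043	210	282	CAUGAAAGAAUGAUGAGUAA	CAGGUGAGAAUGAUGAGGAA	miR2628	mtr-miR2628
EG983630.1	GLE027_H07_025	570	604	UUUAUUCUCAGUUUGUUGCUC	UUUAUUCUCAGUUUUUUGAUC	miR2634	mtr-miR2634
EG982808.1	GLL094_D08_029	586	682	UCUAGUUUGUGUUCAGCAUC	UCUAAUUUGUGUUCACUUUC	miR2866	osa-miR2866
EG988391.1	GLE071_F12_043	404	471	AAGGGGGGGGGGGGAAAGA	AGGGGGAGGGGGGGAAAUU	miR2919	osa-miR2919
EG988087.1	GLE016_B04_015	180	224	UCUCUCUCUCCCUUGAAGGC	UCACUCUCUCCCUUGCAGUU	miR3979	osa-miR3979
EG976112.1	GLL032_G08_026	113	188	UAAGAGAAUUGUAAGUCACU	UCACUGAAUUGUAAGUUACU	miR4413	gma-miR4413b
EG986778.1	GLE057_B04_015	648	710	AGGCAGUGGCUUGGUUAAGGG	AAGCAGUGGCUUGGUCAAGGC	miR4995	gma-miR4995
EG986237.1	GLE051_H12_041	18	76	UCUGUUGUUGUUGGUGUUAUG	UCUGUUGUUGUUGUUGUUGUU	miR5015	ath-miR5015b
EG985015.1	GLE041_B08_031	5	586	UGAGAAGAAGAAGAAGAAAA	GGAGAAGAAGAGAAAGGAAA	miR5021	ath-miR5021
EG990900.1	GLE094_B02_007	644	721	UUUGGAUCUGUUAUUUUGGUAU	UUUCUUUCUGUUAUUUUGGAAU	miR5079	osa-miR5079
EG982261.1	GLL08_B02_007	154	214	AAGUGAUGUUGGAAUGGUUA	UAGUGAAGUUGGAAUAAUUA	miR5265	mtr-miR5265
EG981105.1	GLL079_F09_035	141	268	AGGCAUUUGCUAGAAUACACCCAC	AAGGAUUUGCUAAUAUACACCCAC	miR5267	mtr-miR5267a
EG987890.1	GLE067_G12_042	22	305	UGAAGCUUCAGUUGGUUGUAU	AGAAGCUUCAGUUGGUUUUGA	miR5338	osa-miR5338
EG989431.1	GLE017_D06_021	177	241	CAGGUGUUCUCGAUGGCUUCC	CUAGUGAUUUCGAUGGCUUCC	miR5489	osa-miR5489
EG977779.1	GLL049_B04_015	307	431	UUUGAGAAGGUAUCAUGAGAU	UAUGAGAAUGUAUUAUGAGAU	miR5542	osa-miR5542
EG986048.1	GLE050_B05_023	40	173	UUGUUUGGAUGUUGUCGGA	UUGUUUGGAUGCUGAUGGU	miR5565	sbi-miR5565e
EG983888.1	GLE02_H11_041	113	186	UGGAAGAAGAUGAUAGAAUUA	UGGAAGAAGAUGUGAAAAUUA	miR5641	ath-miR5641
EG985672.1	GLE047_E04_012	293	618	AUGAUGAUGAUGAUGAUGAAA	AUGAUGAUGAAGAAGAAGAAG	miR5658	ath-miR5658
EG984029.1	GLE031_E11_044	110	464	AGAGGUGACCAUUGGAGAUG	AGGGGUGACCGUUGGAGACU	miR5662	ath-miR5662
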