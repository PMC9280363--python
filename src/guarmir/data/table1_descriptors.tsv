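family	au_pct	gc_pct	n_a	n_u	n_g	n_c	n_n	length	mfe	mfei
miR1044	70.13	29.87	39	69	26	20	0	154	-30.3	-0.65
miR1109	69.93	30.07	39	54	23	17	0	133	-27.8	-0.69
miR1132	62.86	37.14	10	12	8	5	0	35	-12.8	-0.98
miR1134	66.08	33.92	20	17	9	10	0	56	-12.5	-0.65
miR1167	58.7	41.3	14	13	11	8	0	46	-16.2	-0.85
miR1313	64.9	35.1	26	35	17	16	0	94	-22.9	-0.69
miR1439	80.07	19.93	240	233	50	68	1	592	-75.3	-0.63
miR1527	63.05	36.95	18	11	7	10	0	46	-11	-0.64
miR1533	83.12	16.88	35	29	8	5	0	77	-9.9	-0.761
miR1535	42.07	57.93	22	39	41	43	0	145	-51.6	-0.61
miR156	56.96	43.04	48	38	31	34	0	151	-38.4	-0.59
miR168	47.92	52.08	12	11	13	12	0	48	-16.6	-0.66
miR169	56.9	43.1	17	16	13	12	0	58	-15.9	-0.63
miR172	62.5	37.5	19	16	9	12	0	56	-14.7	-0.7
miR1852	56.1	43.9	19	26	22	14	1	82	-21.9	-0.6
miR1857	57.78	42.22	9	17	13	6	0	45	-11.8	-0.62
miR2082	52.64	47.36	12	18	19	8	0	57	-18.66	-0.66
miR2098	65.52	34.48	19	38	20	10	0	87	-21.1	-0.7
miR2105	63.81	36.19	30	37	22	16	0	105	-27.7	-0.72
miR2275	47.7	52.3	16	15	16	18	0	65	-21.3	-0.62
miR2606	57.5	42.5	10	13	9	8	0	40	-10.2	-0.6
miR2628	41.09	58.91	21	22	21	9	0	73	-18.6	-0.62
miR2634	74.29	25.71	10	16	5	4	0	35	-12.3	-1.36
miR2866	64.95	35.05	19	43	17	17	1	97	-21.1	-0.62
miR2919	63.24	36.76	21	22	16	9	0	68	-22.2	-0.888
miR393	53.85	46.15	11	17	13	11	0	52	-16.2	-0.67
miR396	61.23	38.77	10	20	10	9	0	49	-16.5	-0.86
miR397	54.17	45.83	8	18	10	12	0	48	-14	-0.63
miR3979	60	40	11	16	8	10	0	45	-11.2	-0.62
miR399	57.15	42.85	14	10	10	8	0	42	-13.3	-0.73
miR414	49.11	50.89	34	21	29	28	0	112	-33.4	-0.6
miR437	58.74	41.26	18	19	16	10	0	63	-21.4	-0.82
miR4413	68.43	31.57	21	31	17	7	0	76	-14.6	-0.6
miR444	63.83	36.17	8	22	10	7	0	47	-10.2	-0.59
miR4995	42.86	57.14	13	14	18	18	0	63	-23.7	-0.65
miR5015	54.24	45.76	9	23	15	12	0	59	-16.9	-0.625
miR5021	50	50	12	11	14	9	0	46	-16.2	-0.7
miR5079	76.93	23.07	25	35	8	10	0	78	-11	-0.61
miR5265	67.22	32.78	24	17	11	9	0	61	-13.8	-0.69
miR5267	68.75	31.25	42	46	21	19	0	128	-37.7	-0.94
miR5338	61.62	38.38	90	85	64	45	0	284	-69	-0.63
miR537	71.43	28.57	12	18	10	2	0	42	-8.3	-0.69
miR5489	52.31	47.69	18	16	18	13	0	65	-20.7	-0.66
miR5542	67.2	32.8	36	48	30	11	0	125	-25.2	-0.6
miR5565	39.55	60.45	35	46	33	20	0	134	-39.6	-0.74
miR5641	70.28	29.72	22	30	14	8	0	74	-21.3	-0.96
miR5658	81.82	18.18	14	22	7	1	0	44	-5.8	-0.72
miR5662	51.84	48.16	108	75	91	80	1	355	-103.2	-0.6
miR773	53.66	46.34	6	16	12	7	0	41	-16.2	-0.85
miR779	57.86	42.14	29	41	33	18	0	121	-31.1	-0.609
miR781	68.19	31.81	9	21	9	5	0	44	-13.1	-0.93
miR837	54.89	45.11	29	44	30	30	0	133	-38.4	-0.63
miR838	49.39	50.61	138	144	150	139	0	571	-177.3	-0.613
miR863	63.64	36.36	13	15	9	7	0	44	-10.8	-0.67
miR865	76.93	23.07	22	18	4	8	0	52	-8.7	-0.72
miR867	81.64	18.36	45	35	9	9	0	98	-17.6	-0.9
miR902	68.86	31.14	20	22	11	8	0	61	-12.7	-0.66
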