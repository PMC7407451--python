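lg_name	duplicated_loci	nonduplicated_loci	female_length_cM	male_length_cM	female_loci	male_loci	lg_type
Cart01	203	510	101.35	87.14	713	224	metacentric
Cart02	380	384	97.77	61.11	764	159	metacentric
Cart03	223	477	93.56	78.98	700	248	metacentric
Cart04	45	547	92.45	67.80	592	194	metacentric
Cart05	272	584	91.73	58.07	856	219	metacentric
Cart06	104	729	91.36	68.95	833	278	metacentric
Cart07	184	496	57.72	60.40	680	204	metacentric
Cart08	182	532	57.56	51.62	714	170	metacentric
Cart09	230	271	64.53	44.47	501	92	acrocentric
Cart10	18	488	63.98	49.68	506	152	acrocentric
Cart11	36	510	63.72	49.41	546	165	acrocentric
Cart12	370	177	63.18	74.69	547	80	acrocentric
Cart13	24	558	62.90	53.67	582	181	acrocentric
Cart14	68	454	62.66	59.74	522	140	acrocentric
Cart15	87	318	62.45	48.26	405	121	acrocentric
Cart16	22	456	62.25	45.80	478	153	acrocentric
Cart17	27	478	62.25	53.19	505	160	acrocentric
Cart18	22	446	61.68	42.08	468	136	acrocentric
Cart19	27	541	61.85	75.08	568	213	acrocentric
Cart20	28	536	60.19	48.36	564	224	acrocentric
Cart21	30	388	59.04	61.23	418	142	acrocentric
Cart22	19	544	58.96	49.49	563	204	acrocentric
Cart23	49	473	58.57	55.39	522	162	acrocentric
Cart24	11	556	58.38	57.23	567	195	acrocentric
Cart25	23	458	58.28	51.08	481	161	acrocentric
Cart26	28	445	58.09	50.91	473	147	acrocentric
Cart27	30	499	58.00	60.69	529	213	acrocentric
Cart28	24	444	57.79	54.44	468	141	acrocentric
Cart29	13	404	57.78	62.64	417	149	acrocentric
Cart30	27	384	57.76	71.50	411	141	acrocentric
Cart31	22	541	56.93	77.82	563	184	acrocentric
Cart32	15	478	56.56	75.17	493	177	acrocentric
Cart33	19	460	56.37	49.57	479	146	acrocentric
Cart34	260	82	55.54	83.66	342	62	acrocentric
Cart35	38	254	54.74	40.54	292	81	acrocentric
Cart36	18	332	54.45	45.50	350	117	acrocentric
Cart37	23	402	53.16	55.82	425	122	acrocentric
Cart38	24	431	50.97	73.21	455	171	acrocentric
Cart39	0	0	0.00	45.13	0	41	acrocentric
Cart40	0	0	0.00	58.46	0	71	acrocentric
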