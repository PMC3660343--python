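lg_id	bes_markers	other_markers	n_markers	length_cm	anchored_mb
LG1	15	23	38	71.527	11.038
LG2	21	22	43	95.398	15.205
LG3	19	20	39	126.716	13.768
LG4	18	16	34	91.198	14.691
LG5	17	15	32	77.483	12.727
LG6	13	19	32	84.551	9.385
LG7	19	16	35	53.407	18.451
LG8	11	14	25	70.365	10.843
LG9	10	13	23	91.522	8.665
LG10	21	13	34	80.977	23.482
LG11	15	13	28	67.203	11.077
LG12	13	14	27	73.801	12.11
LG13	24	19	43	70.092	16.959
LG14	11	11	22	55.163	7.856
LG15	7	14	21	104.901	5.739
LG16	11	17	28	73.158	8.617
LG17	19	10	29	74.529	15.376
LG18	8	11	19	108.209	7.934
LG19	16	11	27	88.88	10.545
LG20	13	11	24	62.509	13.301
LG21	9	11	20	83.293	7.811
LG22	12	19	31	101.361	11.58
LG23	11	15	26	60.024	8.727
LG24	13	9	22	71.157	9.968
LG25	10	8	18	69.281	7.915
LG26	10	10	20	70.518	8.047
LG27	13	13	26	61.281	10.957
LG28	13	7	20	72.796	7.972
LG29	12	14	26	71.95	15.723
LG30	21	16	37	85.511	18.624
LG31	9	23	32	81.673	6.624
LG32	15	7	22	75.25	13.75
LG33	9	9	18	59.809	7.09
LG34	8	10	18	76.005	7.461
LG35	14	6	20	67.051	12.033
LG36	10	8	18	64.688	17.27
LG37	8	7	15	31.54	7.28
LG38	13	7	20	55.411	11.98
LG39	9	11	20	33.866	5.749
LG40	5	7	12	77.752	3.626
LG41	4	4	8	73.751	2.03
LG42	23	9	32	64.868	21.75
LG43	12	7	19	54.718	15.686
LG44	7	13	20	75.497	9.05
LG45	12	12	24	105.152	8.915
LG46	6	5	11	28.436	5.006
LG47	9	5	14	61.469	6.783
LG48	3	4	7	39.198	3.618
LG49	12	10	22	53.701	10.725
LG50	7	1	8	17.315	9.233
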