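disease	group	a	b	c	d	or_printed	ci_low_printed	ci_high_printed
BrCa	overall	286	1400	1427	16606	2.38	2.07	2.73
CRCa	overall	46	1913	346	34117	2.37	1.74	3.24
PrCa	overall	498	1698	1693	12813	2.22	1.98	2.48
AFib	overall	450	2589	2282	31101	2.37	2.12	2.64
CAD	overall	562	3018	2991	29851	1.86	1.69	2.05
T2D	overall	439	2612	2924	30447	1.75	1.57	1.95
BrCa	white	270	1156	1318	13495	2.39	2.07	2.76
CRCa	white	41	1646	312	28717	2.29	1.65	3.19
PrCa	white	468	1448	1544	11017	2.31	2.05	2.59
AFib	white	422	2179	2101	26014	2.40	2.14	2.69
CAD	white	503	2459	2680	25074	1.91	1.73	2.12
T2D	white	367	2284	2159	25906	1.93	1.71	2.17
BrCa	black	7	73	43	1004	2.24	0.97	5.15
CRCa	black	3	83	15	1706	4.11	1.17	14.48
PrCa	black	14	71	74	521	1.39	0.74	2.59
AFib	black	9	137	71	1590	1.47	0.72	3.01
CAD	black	21	177	125	1484	1.41	0.86	2.29
T2D	black	18	57	358	1374	1.21	0.7	2.09
BrCa	asian	1	33	24	405	0.51	0.07	3.9
CRCa	asian	0	35	7	744	0	0	NaN
PrCa	asian	2	36	6	279	2.58	0.5	13.28
AFib	asian	3	62	17	704	2.00	0.57	7.03
CAD	asian	9	51	31	695	3.96	1.79	8.76
T2D	asian	4	49	52	681	1.07	0.37	3.08
BrCa	other	8	138	42	1702	2.35	1.08	5.1
CRCa	other	2	149	12	2950	3.30	0.73	14.88
PrCa	other	14	143	69	996	1.41	0.78	2.58
AFib	other	16	211	93	2793	2.28	1.32	3.94
CAD	other	29	331	155	2598	1.47	0.97	2.22
T2D	other	50	222	355	2486	1.58	1.14	2.19
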