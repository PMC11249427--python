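feature	total_counts	maximum_counts	geometric_mean	arithmetic_mean	p_value	fdr_step_up	ratio	log2_ratio	fold_change
mmu-miR-199a-3p	3358.78	334.02	133.8	146.03	0.00002	0.0056	1.82	0.87	1.82
mmu-miR-29c-3p	85509	9360.88	3354.67	3717.78	0.00035	0.032	1.74	0.8	1.74
mmu-miR-136-5p	39359.5	7158.8	1288.53	1711.28	0.00063	0.041	2.34	1.23	2.34
mmu-miR-361-3p	3335.76	364.41	130.9	145.03	0.001	0.041	1.73	0.79	1.73
mmu-miR-425-5p	7718.57	751.23	313.45	335.59	0.001	0.041	1.58	0.66	1.58
mmu-miR-29a-3p	333859	37810.8	13325.8	14515.6	0.001	0.041	1.62	0.7	1.62
mmu-miR-96-5p	11021.6	2016.63	195.07	479.2	0.0022	0.051	4.1	2.04	4.1
mmu-miR-200a-3p	69763.5	13231.1	1065.51	3033.2	0.003	0.06	4.37	2.13	4.37
mmu-miR-19b-3p	2891.52	260.11	113.63	125.72	0.0032	0.06	1.61	0.69	1.61
mmu-miR-142a-5p	1503.92	111.34	58.02	65.39	0.0033	0.06	1.69	0.76	1.69
mmu-miR-141-3p	17470.2	3787.33	138.34	759.57	0.0044	0.063	4.83	2.27	4.83
mmu-miR-199b-3p	3131.87	316.44	124.42	136.17	0.0046	0.063	1.56	0.65	1.56
mmu-miR-200b-3p	29489.1	7265.54	30.55	1282.14	0.0047	0.063	4.24	2.09	4.24
mmu-miR-770-3p	12717.7	1120.97	496.45	552.94	0.0048	0.063	0.62	-0.7	-1.62
mmu-miR-335-5p	19381.3	2118.16	757.65	842.67	0.0054	0.065	1.6	0.68	1.6
mmu-miR-429-3p	41036.3	9106.46	628.55	1784.19	0.0054	0.065	4.04	2.02	4.04
mmu-miR-194-5p	2893.38	277.05	114.94	125.8	0.0057	0.065	1.57	0.65	1.57
mmu-miR-183-5p	29065.3	7602.77	410.34	1263.71	0.007	0.077	4.09	2.03	4.09
mmu-miR-486b-5p	1028.09	116.61	31.51	44.7	0.011	0.098	1.89	0.92	1.89
mmu-miR-122-5p	1188.32	139.1	45.12	51.67	0.012	0.098	0.62	-0.69	-1.61
mmu-miR-341-3p	4525.72	447.32	177.82	196.77	0.012	0.098	0.65	-0.61	-1.53
mmu-miR-200c-3p	13018.4	4089.48	104.13	566.02	0.016	0.12	3.94	1.98	3.94
mmu-miR-182-5p	28750.4	4820.24	475.58	1250.02	0.016	0.12	3.32	1.73	3.32
mmu-miR-370-3p	10016.9	981.23	91.28	435.52	0.018	0.12	0.66	-0.61	-1.52
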