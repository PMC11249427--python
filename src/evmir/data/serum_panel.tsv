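feature	total_counts	maximum_counts	geometric_mean	arithmetic_mean	p_value	fdr_step_up	ratio	log2_ratio	fold_change
mmu-miR-122-5p	796858.00	264294.00	3438.70	34646.00	0.00088	0.10	0.24	-2.03	-4.08
mmu-miR-671-5p	128563.00	98039.20	17.02	5589.69	0.011	0.59	6.21	2.63	6.21
mmu-miR-486a-5p	1073030.00	175619.00	29390.70	46653.50	0.030	0.67	1.94	0.96	1.94
mmu-miR-486b-5p	1036590.00	167072.00	13981.20	45069.10	0.033	0.67	1.97	0.98	1.97
mmu-miR-451a	179719.00	48373.60	283.56	7813.86	0.039	0.67	2.37	1.25	2.37
mmu-miR-5119	742395.00	230104.00	4465.54	32278.10	0.042	0.67	0.49	-1.02	-2.03
mmu-miR-21a-5p	762960.00	72664.80	5977.85	33172.20	0.044	0.67	0.67	-0.58	-1.50
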