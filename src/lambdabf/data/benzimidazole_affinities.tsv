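# Experimental and computed binding affinities for the 19 2-aminobenzimidazole
# ligands of the riboswitch-like HCV IRES subdomain IIa target.
# kd_um: dissociation constant in micromolar; kd_is_bound = 1 marks a lower
#   bound ("> kd_um"), in which case dg_exp is the corresponding one-sided
#   bound (kcal/mol), not a point value.
# dg_comp_table: final shifted computed dG as published (kcal/mol);
# dg_raw: raw computed dG before the Apo-Holo calibration shift;
# sem: standard error of the mean over the three replicas.
# construct: RNA length used for the experimental measurement.
# NA marks a missing value (ligand 11 left the pocket during plain MD, so no
# alchemical calculation was run for it).
id	kd_um	kd_is_bound	construct	dg_exp	dg_comp_table	dg_raw	sem	note
1	200	1	29mer	-5.04	-0.12	-10.43	0.92	.
2	40	0	29mer	-6.01	-6.65	-16.96	0.68	.
3	8	0	29mer	-6.96	-7.30	-16.88	1.54	.
4	0.86	0	40mer	-8.27	-7.17	-17.48	0.65	.
5	3.50	0	40mer	-7.44	-7.25	-17.56	0.81	.
6	0.72	0	40mer	-8.39	-9.64	-19.95	1.54	.
7	1.70	0	40mer	-7.88	-7.26	-17.57	1.78	.
8	100	0	29mer	-5.45	-4.49	-14.79	0.56	.
9	200	1	29mer	-5.04	-3.56	-13.87	0.53	.
10	125	0	29mer	-5.32	-7.30	-17.61	0.53	.
11	200	1	29mer	-5.04	NA	NA	NA	no_abfe_left_pocket
12	200	1	29mer	-5.04	-0.71	-11.01	1.28	.
13	200	1	29mer	-5.04	1.07	-9.24	1.38	.
14	200	1	29mer	-5.04	2.92	-7.39	1.66	.
15	50	0	29mer	-5.86	-6.73	-17.04	1.03	.
16	10	0	29mer	-6.82	-5.32	-15.63	1.50	.
17	100	1	29mer	-5.04	-2.81	-13.12	1.11	.
18	100	1	29mer	-5.04	1.40	-8.90	0.92	.
19	100	1	29mer	-5.04	3.04	-7.27	0.83	.
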