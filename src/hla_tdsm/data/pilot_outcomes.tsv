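pair_id	group	printed_total_revised_rmsd	observed_grade	note
R-UPN01	retrospective	0.2958	I
R-UPN02	retrospective	0.9975	III
R-UPN03	retrospective	0.3755	II
R-UPN04	retrospective	0.3807	II
R-UPN05	retrospective	0.3680	II	printed as 0.368
R-UPN06	retrospective	0.0838	II
R-UPN07	retrospective	0.4317	IV	HLA-A/B loci recombination case; known discordant
R-UPN08	retrospective	0.6474	IV
R-UPN09	retrospective	0.3750	II
R-UPN10	retrospective	0.6333	IV
R-UPN11	retrospective	0.5059	IV
R-UPN12	retrospective	0.2211	I
P-UPN01	prospective	1.4094	IV
P-UPN02	prospective	0.1363	II
P-UPN03	prospective	0.2579	I	printed 0.2580 in the donor-panel table (0.0929 vs 0.0930 component)
P-UPN04	prospective	0.3976	II	total_discrepant: printed total does not equal component sum 0.4576
P-UPN05	prospective	0.3976	II	total_discrepant: printed total does not equal component sum 0.3808
P-UPN06	prospective	0.1832	I
P-UPN07	prospective	0.1102	I
P-UPN10	prospective	0.4472	II
P-UPN11	prospective	0.7544	IV
P-UPN12	prospective	0.3755	II
P-UPN13	prospective	1.2944	IV
P-UPN14	prospective	0.0403	I
P-UPN15	prospective	0.8127	III
P-UPN16	prospective	0.2595	I
P-UPN17	prospective	0.7682	III
P-UPN18	prospective	0.5978	IV
P-UPN19	prospective	0.8322	IV
P-UPN20	prospective	0.7627	IV
P-UPN21	prospective	0.1472	II
P-UPN22	prospective	0.6499	III
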