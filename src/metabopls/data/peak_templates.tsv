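# Default 1H chemical-shift peak templates for the simulated rat-brain cohort.
# Shifts follow standard aqueous-solution reference values (HMDB); the lactate
# CH3 doublet centre at 1.325 ppm is the chemical-shift reference.
# relative_intensity is proportional to the number of contributing protons.
# Editable: metabolite <TAB> kegg_id <TAB> center_ppm <TAB> relative_intensity <TAB> halfwidth_ppm
metabolite	kegg_id	center_ppm	relative_intensity	halfwidth_ppm
Lactate	C00186	1.325	3.0	0.005
Lactate	C00186	4.11	1.0	0.005
NAA	C01042	2.01	3.0	0.005
NAA	C01042	2.49	1.0	0.005
NAA	C01042	2.67	1.0	0.005
Creatine	C00300	3.03	3.0	0.005
Creatine	C00300	3.93	2.0	0.005
Acetate	C00033	1.91	3.0	0.005
GABA	C00334	1.89	2.0	0.005
GABA	C00334	2.28	2.0	0.005
GABA	C00334	3.01	2.0	0.005
Phosphorylcholine	C00588	3.21	9.0	0.005
Choline	C00114	3.19	9.0	0.005
L-Valine	C00183	0.98	3.0	0.005
L-Valine	C00183	1.03	3.0	0.005
L-Alanine	C00041	1.47	3.0	0.005
L-Glutamate	C00025	2.04	2.0	0.005
L-Glutamate	C00025	2.34	2.0	0.005
L-Glutamine	C00064	2.13	2.0	0.005
L-Glutamine	C00064	2.44	2.0	0.005
L-Aspartate	C00049	2.68	1.0	0.005
L-Aspartate	C00049	2.80	1.0	0.005
Myo-inositol	C00137	3.27	1.0	0.005
Myo-inositol	C00137	3.52	2.0	0.005
Myo-inositol	C00137	3.61	2.0	0.005
Myo-inositol	C00137	4.05	1.0	0.005
Taurine	C00245	3.25	2.0	0.005
Taurine	C00245	3.42	2.0	0.005
Succinate	C00042	2.41	4.0	0.005
Scyllo-inositol	C06153	3.34	6.0	0.005
L-Serine	C00065	3.84	1.0	0.005
L-Serine	C00065	3.96	2.0	0.005
Citrate	C00158	2.54	2.0	0.005
Citrate	C00158	2.66	2.0	0.005
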