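# Chemical-shift annotation library: half-open ppm windows per metabolite.
# Windows are +/- 0.015 ppm around standard 1H resonance positions (HMDB);
# overlapping windows across metabolites are legitimate and are reported as
# ambiguous assignments, never silently resolved.
# Editable: metabolite <TAB> kegg_id <TAB> lo_ppm <TAB> hi_ppm
metabolite	kegg_id	lo_ppm	hi_ppm
Lactate	C00186	1.310	1.340
Lactate	C00186	4.095	4.125
NAA	C01042	1.995	2.025
NAA	C01042	2.475	2.505
NAA	C01042	2.655	2.685
Creatine	C00300	3.015	3.045
Creatine	C00300	3.915	3.945
Acetate	C00033	1.895	1.925
GABA	C00334	1.875	1.905
GABA	C00334	2.265	2.295
GABA	C00334	2.995	3.025
Phosphorylcholine	C00588	3.195	3.225
Choline	C00114	3.175	3.205
L-Valine	C00183	0.965	0.995
L-Valine	C00183	1.015	1.045
L-Alanine	C00041	1.455	1.485
L-Glutamate	C00025	2.025	2.055
L-Glutamate	C00025	2.325	2.355
L-Glutamine	C00064	2.115	2.145
L-Glutamine	C00064	2.425	2.455
L-Aspartate	C00049	2.665	2.695
L-Aspartate	C00049	2.785	2.815
Myo-inositol	C00137	3.255	3.285
Myo-inositol	C00137	3.505	3.535
Myo-inositol	C00137	3.595	3.625
Myo-inositol	C00137	4.035	4.065
Taurine	C00245	3.235	3.265
Taurine	C00245	3.405	3.435
Succinate	C00042	2.395	2.425
Scyllo-inositol	C06153	3.325	3.355
L-Serine	C00065	3.825	3.855
L-Serine	C00065	3.945	3.975
Citrate	C00158	2.525	2.555
Citrate	C00158	2.645	2.675
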