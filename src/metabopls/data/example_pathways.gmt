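Alanine and aspartate metabolism	synthetic example pathway set	C00041	C00049	C00025	C00064	C00158	C00042	C90001	C90002	C90003	C90004	C90005	C90006
Glutamate metabolism	synthetic example pathway set	C00025	C00064	C00334	C00049	C90007	C90008	C90009	C90010
GABA receptor signaling	synthetic example pathway set	C00334	C00042	C90011	C90012	C90013	C90014	C90015
Glycine, serine and threonine metabolism	synthetic example pathway set	C00065	C00300	C00114	C90016	C90017	C90018	C90019	C90020	C90021
Citrate cycle	synthetic example pathway set	C00158	C00042	C00025	C90022	C90023	C90024	C90025	C90026
Taurine and hypotaurine metabolism	synthetic example pathway set	C00245	C00065	C90027	C90028	C90029
Inositol phosphate metabolism	synthetic example pathway set	C00137	C06153	C90030	C90031	C90032	C90033
Glycolysis and pyruvate metabolism	synthetic example pathway set	C00186	C00033	C00041	C90034	C90035	C90036	C90037
Valine, leucine and isoleucine degradation	synthetic example pathway set	C00183	C90038	C90039	C90040	C90041	C90042
Glycerophospholipid metabolism	synthetic example pathway set	C00114	C00588	C90043	C90044	C90045	C90046	C90047
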