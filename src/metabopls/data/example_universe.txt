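# synthetic example universe: every ID known to the example pathway collection plus background compounds
C00186
C01042
C00300
C00033
C00334
C00588
C00114
C00183
C00041
C00025
C00064
C00049
C00137
C00245
C00042
C06153
C00065
C00158
C90001
C90002
C90003
C90004
C90005
C90006
C90007
C90008
C90009
C90010
C90011
C90012
C90013
C90014
C90015
C90016
C90017
C90018
C90019
C90020
C90021
C90022
C90023
C90024
C90025
C90026
C90027
C90028
C90029
C90030
C90031
C90032
C90033
C90034
C90035
C90036
C90037
C90038
C90039
C90040
C90041
C90042
C90043
C90044
C90045
C90046
C90047
C80001
C80002
C80003
C80004
C80005
C80006
C80007
C80008
C80009
C80010
C80011
C80012
C80013
C80014
C80015
C80016
C80017
C80018
C80019
C80020
C80021
C80022
C80023
C80024
C80025
C80026
C80027
C80028
C80029
C80030
C80031
C80032
C80033
C80034
C80035
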