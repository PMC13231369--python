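solute,m_B,a_e6,b_e6,c_abs_e6,c_sign,ard_sigma
l-threonine,0.000,77.70,0.00915,0.00016,1,0.00356
l-threonine,0.100,78.03,0.01177,0.00015,1,0.00575
l-threonine,0.200,78.36,0.01451,0.00013,1,0.00215
l-threonine,0.300,78.69,0.02148,0.00040,1,0.08176
l-threonine,0.400,79.05,0.02492,0.00022,1,0.00373
glycyl-l-threonine,0.000,108.78,0.05113,0.00056,-1,0.00147
glycyl-l-threonine,0.100,108.90,0.04816,0.00032,-1,0.00246
glycyl-l-threonine,0.200,109.03,0.04541,0.00008,-1,0.00385
glycyl-l-threonine,0.300,109.14,0.04287,0.00015,1,0.08472
glycyl-l-threonine,0.400,109.30,0.04198,0.00014,1,0.00583
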