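solute,m_B,E_288.15,E_298.15,E_308.15,E_318.15,dE_dT_abs
l-threonine,0.000,0.00602,0.00915,0.01227,0.01539,0.00031
l-threonine,0.100,0.00885,0.01177,0.01468,0.01760,0.00029
l-threonine,0.200,0.01182,0.01451,0.01721,0.01990,0.00027
l-threonine,0.300,0.01345,0.02148,0.02950,0.03753,0.00080
l-threonine,0.400,0.02059,0.02492,0.02926,0.03360,0.00043
glycyl-l-threonine,0.000,0.06235,0.05113,0.03991,0.02869,0.00112
glycyl-l-threonine,0.100,0.05450,0.04816,0.04183,0.03549,0.00063
glycyl-l-threonine,0.200,0.04699,0.04541,0.04384,0.04227,0.00016
glycyl-l-threonine,0.300,0.03980,0.04287,0.04594,0.04901,0.00031
glycyl-l-threonine,0.400,0.03923,0.04198,0.04473,0.04748,0.00028
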