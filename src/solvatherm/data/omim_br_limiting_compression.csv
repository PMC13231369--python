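solute,m_B,T,K0_e6,se_K0_e6,Sk_e6,se_Sk_e6
l-threonine,0.000,288.15,-37.8995,0.0079,0.8249,0.0145
l-threonine,0.000,298.15,-29.6277,0.0103,-0.0456,0.0187
l-threonine,0.000,308.15,-26.5794,0.0106,-0.2941,0.0193
l-threonine,0.000,318.15,-26.4624,0.0104,-0.2643,0.0190
l-threonine,0.100,288.15,-28.9426,0.0115,-0.1192,0.0184
l-threonine,0.100,298.15,-27.3074,0.0114,-0.1944,0.0182
l-threonine,0.100,308.15,-26.1867,0.0113,-0.2445,0.0180
l-threonine,0.100,318.15,-25.6219,0.0112,-0.2705,0.0179
l-threonine,0.200,288.15,-27.0925,0.0110,-0.2219,0.0177
l-threonine,0.200,298.15,-25.6912,0.0108,-0.2838,0.0174
l-threonine,0.200,308.15,-24.7283,0.0107,-0.3254,0.0173
l-threonine,0.200,318.15,-24.2933,0.0107,-0.3454,0.0171
l-threonine,0.300,288.15,-25.3421,0.0110,-0.3157,0.0177
l-threonine,0.300,298.15,-24.1529,0.0108,-0.3663,0.0175
l-threonine,0.300,308.15,-24.9597,0.0105,-0.2439,0.0169
l-threonine,0.300,318.15,-22.8548,0.0107,-0.4309,0.0177
l-threonine,0.400,288.15,-23.6879,0.0111,-0.3985,0.0177
l-threonine,0.400,298.15,-22.6906,0.0109,-0.4395,0.0175
l-threonine,0.400,308.15,-24.6147,0.0104,-0.2176,0.0166
l-threonine,0.400,318.15,-21.7933,0.0108,-0.4787,0.0173
glycyl-l-threonine,0.000,288.15,-55.0303,0.0003,1.1719,0.0060
glycyl-l-threonine,0.000,298.15,-44.7933,0.0004,-0.3818,0.0068
glycyl-l-threonine,0.000,308.15,-38.5984,0.0004,-1.1860,0.0070
glycyl-l-threonine,0.000,318.15,-33.0062,0.0004,-1.8929,0.0072
glycyl-l-threonine,0.100,288.15,-51.5021,0.0004,0.7740,0.0069
glycyl-l-threonine,0.100,298.15,-42.6202,0.0004,-0.5392,0.0077
glycyl-l-threonine,0.100,308.15,-36.8072,0.0005,-1.2913,0.0079
glycyl-l-threonine,0.100,318.15,-31.5376,0.0005,-1.9585,0.0080
glycyl-l-threonine,0.200,288.15,-48.7592,0.0003,0.5138,0.0061
glycyl-l-threonine,0.200,298.15,-40.5480,0.0004,-0.6933,0.0067
glycyl-l-threonine,0.200,308.15,-34.5498,0.0004,-1.4767,0.0069
glycyl-l-threonine,0.200,318.15,-30.1259,0.0004,-2.0283,0.0070
glycyl-l-threonine,0.300,288.15,-46.1586,0.0003,0.2803,0.0060
glycyl-l-threonine,0.300,298.15,-38.5723,0.0004,-0.8293,0.0065
glycyl-l-threonine,0.300,308.15,-33.4515,0.0004,-1.4894,0.0067
glycyl-l-threonine,0.300,318.15,-28.7695,0.0004,-2.0862,0.0068
glycyl-l-threonine,0.400,288.15,-43.6921,0.0003,0.0666,0.0063
glycyl-l-threonine,0.400,298.15,-36.6079,0.0004,-0.9661,0.0068
glycyl-l-threonine,0.400,308.15,-31.8805,0.0004,-1.5731,0.0069
glycyl-l-threonine,0.400,318.15,-27.4660,0.0004,-2.1387,0.0070
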