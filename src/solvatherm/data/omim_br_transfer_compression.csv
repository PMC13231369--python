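solute,m_B,T,dK0_e6
l-threonine,0.100,288.15,8.9570
l-threonine,0.100,298.15,2.3203
l-threonine,0.100,308.15,0.3927
l-threonine,0.100,318.15,0.8405
l-threonine,0.200,288.15,10.8071
l-threonine,0.200,298.15,3.9364
l-threonine,0.200,308.15,1.8511
l-threonine,0.200,318.15,2.1690
l-threonine,0.300,288.15,12.5575
l-threonine,0.300,298.15,5.4747
l-threonine,0.300,308.15,1.6197
l-threonine,0.300,318.15,3.6076
l-threonine,0.400,288.15,14.2117
l-threonine,0.400,298.15,6.9370
l-threonine,0.400,308.15,1.9647
l-threonine,0.400,318.15,4.6691
glycyl-l-threonine,0.100,288.15,3.5282
glycyl-l-threonine,0.100,298.15,2.1731
glycyl-l-threonine,0.100,308.15,1.7912
glycyl-l-threonine,0.100,318.15,1.4687
glycyl-l-threonine,0.200,288.15,6.2711
glycyl-l-threonine,0.200,298.15,4.2453
glycyl-l-threonine,0.200,308.15,4.0485
glycyl-l-threonine,0.200,318.15,2.8804
glycyl-l-threonine,0.300,288.15,8.8716
glycyl-l-threonine,0.300,298.15,6.2210
glycyl-l-threonine,0.300,308.15,5.1469
glycyl-l-threonine,0.300,318.15,4.2367
glycyl-l-threonine,0.400,288.15,11.3381
glycyl-l-threonine,0.400,298.15,8.1854
glycyl-l-threonine,0.400,308.15,6.7179
glycyl-l-threonine,0.400,318.15,5.5403
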