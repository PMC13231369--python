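solute,T,V_AB_e6,V_ABB_e6,K_AB,K_ABB
l-threonine,288.15,15.43,-13.91,405.0807,-3931.9461
l-threonine,298.15,16.81,-11.77,113.8927,-465.6714
l-threonine,308.15,17.19,-31.95,46.0321,-360.2083
l-threonine,318.15,21.77,-40.66,48.9420,177.0828
glycyl-l-threonine,288.15,9.58,-15.54,175.6968,-579.3466
glycyl-l-threonine,298.15,4.41,-31.38,109.7760,-126.5718
glycyl-l-threonine,308.15,7.00,-9.01,104.8075,-356.1396
glycyl-l-threonine,318.15,8.21,-7.75,74.7684,-92.0147
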