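line,delta_pi,a1,b1,b2,bp1,bp2,g1,g2,g3,g4,g5
MBON-s01,-0.44,0,5,3,0,0,0,0,0,0,0
MBON-s02,-0.30,0,0,4,0,4,0,0,0,0,0
MBON-s03,-0.18,4,0,0,3,0,0,0,0,0,0
MBON-s04,-0.05,0,0,0,0,3,0,1,0,4,0
MBON-s05,0.09,0,0,0,0,0,5,4,1,0,0
MBON-s06,0.26,0,0,0,0,0,0,0,3,5,4
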