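line,delta_pi,a1,b1,b2,bp1,bp2,g1,g2,g3,g4,g5
PAM-s01,0.52,0,4,5,0,1,0,0,0,0,0
PAM-s02,0.38,0,1,4,0,3,0,0,0,0,1
PAM-s03,0.24,3,0,2,4,0,0,0,0,1,0
PAM-s04,0.11,0,0,1,0,4,0,0,1,3,0
PAM-s05,-0.06,0,0,0,0,0,4,3,0,0,1
PAM-s06,-0.21,0,1,0,0,0,0,0,4,4,3
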