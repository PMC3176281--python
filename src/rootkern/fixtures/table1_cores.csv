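core_id,max_depth_cm,total_root_mass_g,frac_mass_sequenced,n_fragments,richness
A,20,2.34,0.11,4,4
B,20,1.49,0.11,5,4
C,100,0.73,0.11,10,6
D,100,6.10,0.08,3,3
E,20,2.64,0.03,10,1
F,300,1.82,0.16,12,7
G,20,1.23,0.17,12,4
H,100,3.58,0.05,22,9
I,100,4.30,0.24,16,4
J,20,1.72,0.09,10,4
K,20,2.56,0.06,9,6
L,20,5.74,0.19,7,4
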