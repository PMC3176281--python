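core_id,x_m,y_m
A,12,12
B,12,52
C,12,92
D,32,32
E,32,72
F,52,12
G,52,52
H,52,92
I,72,32
J,72,72
K,92,12
L,92,52
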