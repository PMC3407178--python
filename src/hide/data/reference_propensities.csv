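aa,helix,sheet,loop,hinge
A,1.46,0.87,0.71,1.00
C,0.93,1.37,0.84,0.97
D,0.96,0.54,1.31,0.87
E,1.46,0.65,0.85,0.89
F,1.04,1.44,0.70,0.88
G,0.42,0.36,1.85,0.96
H,0.85,1.16,1.02,0.89
I,0.86,1.85,0.59,0.76
K,1.12,0.86,0.99,1.24
L,1.32,1.15,0.65,0.76
M,1.39,0.76,0.83,0.41
N,0.75,0.66,1.40,1.21
P,0.55,0.35,1.75,1.83
Q,1.25,0.81,0.92,1.10
R,1.17,0.88,0.94,0.86
S,0.68,0.90,1.31,1.41
T,0.78,1.29,0.99,1.02
V,0.84,1.90,0.58,0.82
W,1.13,1.19,0.78,0.86
Y,0.98,1.39,0.78,1.02
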