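# Van der Waals radii (A) used for solvent accessibility, Bondi-style values.
# Elements absent from this table raise a configuration error naming them;
# extend here rather than in code.
C: 1.70
N: 1.55
O: 1.52
S: 1.80
P: 1.80
SE: 1.90
F: 1.47
CL: 1.75
BR: 1.85
I: 1.98
MG: 1.73
ZN: 1.39
MN: 1.73
FE: 1.72
NA: 2.27
K: 2.75
CA: 2.31
H: 1.20
D: 1.20
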