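> CTCF_synthetic
# synthetic consensus-derived stand-in for a CTCF position frequency matrix (not a database motif)
# consensus TGGCCACCAGGGGGCGCTA; column totals 100
A 10 10 10 10 10 70 10 10 70 10 10 10 10 10 10 10 10 10 70
C 10 10 10 70 70 10 70 70 10 10 10 10 10 10 70 10 70 10 10
G 10 70 70 10 10 10 10 10 10 70 70 70 70 70 10 70 10 10 10
T 70 10 10 10 10 10 10 10 10 10 10 10 10 10 10 10 10 70 10
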