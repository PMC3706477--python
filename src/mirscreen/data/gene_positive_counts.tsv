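gene	positive_mirnas
CYP3A4	9
TP53	10
PTEN	18
TRF2	23
FSCN1	24
MXI1	31
POT1	12
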