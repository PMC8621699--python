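#source: per-nucleotide hydrogen-bonding contact propensity derived from RNA-protein complex statistics (placeholder values; replace with the published lncPro/Morozova tables for parity with the original pipeline)
A	0.31
C	0.21
G	0.29
U	0.19
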