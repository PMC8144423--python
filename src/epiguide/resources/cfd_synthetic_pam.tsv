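# SYNTHETIC PAM-dinucleotide penalties (stand-in values).
dinucleotide	penalty
AA	0.02
AC	0.02
AG	0.3
AT	0.02
CA	0.02
CC	0.02
CG	0.1
CT	0.02
GA	0.2
GC	0.05
GG	1.0
GT	0.1
TA	0.02
TC	0.02
TG	0.1
TT	0.02
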