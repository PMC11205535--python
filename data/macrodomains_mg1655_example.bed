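# Example macrodomain intervals for E. coli MG1655 (U00096.3, 4,641,652 bp).
# Literature-derived, rounded to 10 kb and simplified to non-wrapping
# intervals; user-verifiable and intended as a template, not as a
# reference annotation.  Columns: chrom, start, end, name (0-based,
# half-open).
chr	0	1100000	Right
chr	1100000	2040000	Ter
chr	2040000	2920000	Left
chr	2920000	3620000	NS-left
chr	3620000	4430000	Ori
chr	4430000	4641652	NS-right
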