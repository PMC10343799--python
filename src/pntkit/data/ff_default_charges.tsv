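# Default partial charge set, version 1.
# Zwitterion: +1 e over the N-terminal NH3 group, -1 e over the carboxylate,
# small backbone partials on the first carbonyl.  Unlisted atoms carry 0.
# Columns: residue-ordinal-within-unit, atom name, charge (e).
residue	atom	charge
1	N	0.10
1	H1	0.30
1	H2	0.30
1	H3	0.30
1	C	0.25
1	O	-0.25
1	CA	0.10
1	HA	-0.10
2	C	0.20
2	O	-0.60
2	OXT	-0.60
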