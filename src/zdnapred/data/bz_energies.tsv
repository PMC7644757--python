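# Dinucleotide B->Z transition free energies (kcal/mol per dinucleotide,
# anti/syn context) following the Z-Hunt energetics: alternating d(CG) is the
# most Z-prone step, d(AT) the least; junction costs are the free-energy
# penalties of one B-Z and one Z-Z boundary.
# bz_junction = 5.0
# zz_junction = 4.0
dinucleotide	energy
AA	3.9
AC	3.4
AG	3.4
AT	5.9
CA	1.4
CC	2.4
CG	0.66
CT	3.4
GA	3.4
GC	4.0
GG	2.4
GT	3.4
TA	2.5
TC	3.4
TG	1.4
TT	3.9
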