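# Synthetic RIBOSUM-style log-odds scores for canonical RNA pair types.
# Constructed for this package (no published matrix is redistributed here):
# values are patterned on the ribosomal-RNA-derived RIBOSUM family of
# matrices -- conserved pairs score highest, compensatory double
# substitutions (e.g. GC<->AU) score clearly positive, single wobble shifts
# less so -- but the numbers are this package's own. Symmetric, units are
# arbitrary log-odds.
	AU	CG	GC	GU	UA	UG
AU	4.5	1.7	2.7	1.3	2.0	0.6
CG	1.7	5.4	2.1	0.6	1.3	-0.3
GC	2.7	2.1	5.6	1.2	1.8	0.4
GU	1.3	0.6	1.2	4.9	0.3	2.0
UA	2.0	1.3	1.8	0.3	5.0	1.2
UG	0.6	-0.3	0.4	2.0	1.2	4.8
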