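# Allocation of the 25 initial-model configurations (orientation x n-shift)
# to full-dimer vs truncated-dimer scope: 10 full + 15 truncated.
# Orientations: A both chains to the K1 face; B both to the K10 face;
# C each chain onto the opposite chain face; D each onto its own face;
# E fully extended (not folded back).
# Editable reconstruction: the published per-cell scope assignment is given
# only graphically, so any 10/15 split over the 25 distinct cells is valid
# input here.
orientation	n_shift	scope
A	0	full
A	5	full
B	0	full
B	5	full
C	0	full
C	5	full
D	0	full
D	5	full
E	0	full
E	5	full
A	-5	truncated
A	3	truncated
A	10	truncated
B	-5	truncated
B	3	truncated
B	10	truncated
C	-5	truncated
C	3	truncated
C	10	truncated
D	-5	truncated
D	3	truncated
D	10	truncated
E	-5	truncated
E	3	truncated
E	10	truncated
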