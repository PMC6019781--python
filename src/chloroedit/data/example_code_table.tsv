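# SYNTHETIC example recognition-code table — invented values for testing and
# demonstration only; NOT a published derivation.  Columns: the amino acids at
# motif positions 5 and last, then log-likelihood ratios for each RNA base.
aa5	aa_last	A	C	G	U
T	N	1.40	-0.60	-1.10	-0.70
T	D	-0.50	-0.90	1.30	-0.60
S	N	-0.40	-0.70	-1.00	1.20
N	D	-0.80	-0.30	-0.90	1.10
N	S	-0.60	1.20	-1.00	-0.50
N	N	-0.20	0.80	-0.70	0.30
S	D	-0.30	-0.40	0.20	0.90
T	S	0.30	0.70	-0.80	-0.40
N	T	0.90	-0.20	-0.60	-0.30
S	S	-0.10	0.60	-0.50	0.20
P	G	0.10	-0.10	0.40	-0.20
G	D	-0.70	-0.20	1.00	-0.40
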