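# Enzyme cleavage rules: bond C-terminal to a P1 residue is cut unless the
# P1' residue is in the veto set.
# The subtilisin A residue sets are not published; this entry is the
# minimal-complexity rule recovered by wortpep.reference.recover_subtilisin_rule
# from the six published per-protein hydrolysed-bond counts.
name	ec_number	p1_residues	p1prime_block
subtilisin A	3.4.21.62	AFGIKLMV	ACGHKMR
trypsin	3.4.21.4	KR	P
chymotrypsin (high specificity)	3.4.21.1	FWY	P
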