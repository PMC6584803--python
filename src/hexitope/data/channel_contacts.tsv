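# Interaction probabilities (% of analyzed simulation time within 2 Å) of
# hCx26 hemichannel residues with the abEC1.1 antibody, per protomer (P1-P4;
# the P4-P6 pattern repeats by symmetry for the second antibody) and
# extracellular loop.  Bundled reference data: the underlying trajectory is
# not redistributable, so these values are fixture inputs here, covered by
# parameter-recovery tests rather than recomputation.
protomer	region	residue	number	probability_pct
P1	EC1	ASN	54	82
P1	EC1	THR	55	56
P1	EC1	LEU	56	85
P1	EC2	PRO	175	29
P2	EC1	CYS	53	10
P2	EC1	ASN	54	92
P2	EC1	THR	55	82
P2	EC1	LEU	56	100
P2	EC1	GLN	57	78
P2	EC1	PRO	58	31
P2	EC2	PRO	173	2
P2	EC2	PRO	175	68
P2	EC2	ASN	176	21
P2	EC2	THR	177	4
P2	EC2	VAL	178	2
P3	EC1	ASN	54	63
P3	EC1	THR	55	7
P3	EC1	LEU	56	100
P3	EC1	GLN	57	65
P3	EC1	PRO	58	7
P3	EC2	TRP	172	12
P3	EC2	PRO	173	7
P3	EC2	PRO	175	43
P3	EC2	ASN	176	56
P3	EC2	THR	177	68
P4	EC1	THR	55	2
P4	EC1	LEU	56	85
P4	EC1	GLN	57	90
P4	EC1	PRO	58	73
P4	EC2	PRO	175	14
P4	EC2	ASN	176	5
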