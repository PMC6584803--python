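# Interaction probabilities (% of analyzed simulation time within 2 Å) of
# abEC1.1 antibody residues with the extracellular domain of the hCx26
# hemichannel, by chain (heavy HC / light LC) and region (constant region or
# complementarity-determining region).  Bundled reference data; see
# channel_contacts.tsv for provenance notes.
chain	region	residue	number	probability_pct
HC	CONST	SER	27	19
HC	CONST	ASN	76	14
HC	CONST	SER	77	5
HC	CONST	ASN	79	2
HC	CDR1	GLY	28	29
HC	CDR1	PHE	29	53
HC	CDR1	THR	30	100
HC	CDR1	SER	32	70
HC	CDR1	SER	33	98
HC	CDR1	TYR	34	98
HC	CDR2	HIS	55	73
HC	CDR3	PHE	102	78
HC	CDR3	SER	103	90
HC	CDR3	TRP	104	100
HC	CDR3	ARG	105	17
LC	CONST	TYR	178	80
LC	CONST	THR	182	98
LC	CONST	ARG	183	93
LC	CONST	ALA	184	58
LC	CONST	THR	185	85
LC	CONST	GLY	186	68
LC	CONST	ILE	187	43
LC	CONST	PRO	188	63
LC	CONST	ASP	189	85
LC	CDR1	SER	160	5
LC	CDR2	GLY	179	2
LC	CDR2	SER	181	37
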