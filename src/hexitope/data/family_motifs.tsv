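# Epitope-region motifs of the 20 human connexin isoforms: EC1 residues
# 54-58 and EC2 residues 175-176 (hCx26 numbering).  Bundled reference data
# for the abEC1.1 antibody selectivity analysis; gene symbols are kept as
# printed in the source table, including "CJB7" (hCx25) and "GJG3" (hCx30.2)
# even though the electrophysiology for the latter is reported under the
# name hCx30.2/31.3 (GJC3) — the discrepancy is flagged, not resolved.
gene	protein	ec1_motif	ec2_motif	note
GJB2	hCx26	NTLQP	PN	reference isoform
GJB6	hCx30	NTLQP	PN	position 177 is Leu; antibody contact there is main-chain only
GJB1	hCx32	NTLQP	PN
GJB4	hCx30.3	NTKQP	PH
GJD3	hCx31.9	NTLQP	PH
GJA8	hCx50	NTQQP	PN
GJA3	hCx46	NTQQP	PN
GJA10	hCx62	NTRQP	PN
GJB5	hCx31.1	NTRQP	PN
GJB3	hCx31	NTKQP	PN
GJA9	hCx59	NTEQP	PN
GJC2	hCx47	NTRQP	PH
GJA1	hCx43	NTQQP	PH
GJA5	hCx40	DTIQP	PH
GJD4	hCx40.1	NTLQP	TG
GJC1	hCx45	NTEQP	PH
GJD2	hCx36	NTLQP	IK
GJG3	hCx30.2	HTQQP	LG	measured electrophysiologically as hCx30.2/31.3 (GJC3)
CJB7	hCx25	NSRQP	PN	gene symbol as printed in the source table
GJA4	hCx37	NTAQP	PY
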