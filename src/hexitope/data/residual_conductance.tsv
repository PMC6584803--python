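# Residual hemichannel membrane conductance after abEC1.1 application
# (952 nM, 15 min), as % of the pre-application control conductance, for
# HeLa DH transfectants expressing each connexin isoform.  Bundled reference
# data: raw recordings are unavailable, so these percentages serve as the
# measured side of the prediction-concordance analysis.
isoform	residual_pct	note
hCx26	16.8	from prior characterization of the same antibody
hCx32	16
hCx30	25
hCx30.2/31.3	91	named hCx30.2 (GJG3) in the motif table
hCx30.3	82
hCx31	87
hCx31.1	73
hCx37	73
hCx43	73
hCx45	98
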