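# Acid dissociation constants for peptide ionizable groups, one row per
# (set, group). sign = charge carried by the protonated (+) or deprotonated (-)
# form. IPC_peptide: Kozlowski, Biol Direct 11:55 (2016), peptide-optimised set.
# EMBOSS: Rice et al., Trends Genet 16:276-277 (2000), iep defaults.
set	group	pka	sign
IPC_peptide	n_term	9.564	+
IPC_peptide	c_term	2.383	-
IPC_peptide	D	3.887	-
IPC_peptide	E	4.317	-
IPC_peptide	C	8.297	-
IPC_peptide	Y	10.071	-
IPC_peptide	H	6.018	+
IPC_peptide	K	10.517	+
IPC_peptide	R	12.503	+
EMBOSS	n_term	8.6	+
EMBOSS	c_term	3.6	-
EMBOSS	D	3.9	-
EMBOSS	E	4.1	-
EMBOSS	C	8.5	-
EMBOSS	Y	10.1	-
EMBOSS	H	6.5	+
EMBOSS	K	10.8	+
EMBOSS	R	12.5	+
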