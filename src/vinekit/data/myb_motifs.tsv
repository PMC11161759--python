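motif_id	consensus	note
MYBCORE	CNGTTR	generic plant MYB core recognition element
MBS	CAACTG	MYB binding site involved in drought-inducibility
MYBPLANT	MACCWAMC	consensus of P-type MYB sites in phenylpropanoid gene promoters
MYBPZM	CCWACC	maize P factor core, flavonoid pathway promoters
MBSII	AAAAGTTAGTTA	MYB binding site II variant
AC_ELEMENT	ACCWWCC	AC-rich element bound by R2R3-MYBs
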