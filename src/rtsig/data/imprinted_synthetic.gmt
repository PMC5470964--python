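IMPRINTED_SYNTHETIC	synthetic stand-in list of human imprinted genes (not the published catalogue)	H19	IGF2	IGF2-AS	MEG3	MEG8	DLK1	RTL1	SNRPN	SNURF	NDN	MAGEL2	MKRN3	UBE3A	KCNQ1OT1	CDKN1C	PHLDA2	SLC22A18	PLAGL1	HYMAI	PEG3	ZIM2	PEG10	SGCE	MEST	GRB10	NNAT	BLCAP	GNAS	GNAS-AS1	ZDBF2	NAP1L5	RB1	DIRAS3	L3MBTL1	TP73
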