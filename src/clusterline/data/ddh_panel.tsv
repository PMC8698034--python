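strain_a	strain_b	metric	value	note
# Pairwise relatedness panel: digital DNA-DNA hybridization (dDDH) values
# annotated on the 16S tree plus the gyrB marker identities reported in the
# taxonomy analysis.  Values printed only as a bound or range in the source
# are stored at a representative point inside the bound and flagged
# approximate in the note.
Micromonospora sp. B006	M. tulbaghiae DSM 45142	dDDH	51
Micromonospora sp. L5	M. aurantiaca ATCC 27029	dDDH	91	approximate: printed as >90
Micromonospora sp. RV43	M. aurantiaca ATCC 27029	dDDH	91	approximate: printed as >90
Micromonospora sp. WMMB235	M. aurantiaca ATCC 27029	dDDH	91	approximate: printed as >90
Micromonospora sp. CNZ297	M. aurantiaca ATCC 27029	dDDH	91	approximate: printed as >90
Micromonospora sp. CNZ296	M. aurantiaca ATCC 27029	dDDH	91	approximate: printed as >90
M. globosa NRRL B-2673	M. aurantiaca ATCC 27029	dDDH	91	approximate: printed as >90
Micromonospora sp. M42	M. chalcea DSM 43026	dDDH	90	approximate: printed as ~90
Micromonospora sp. DSW705	M. chalcea DSM 43026	dDDH	90	approximate: printed as ~90
Micromonospora sp. WMMA2032	M. sediminicola DSM 45794	dDDH	37
Micromonospora sp. DSW705	Micromonospora sp. TSRI0369	dDDH	64
M. parva NRRL B-2680	M. chokoriensis NRRL B-24750	dDDH	65	approximate: printed as <70
M. saelicesensis DSM 44871	Micromonospora sp. CNZ322	dDDH	71
Micromonospora sp. NRRL B-16802	M. profundi DSM 45981	dDDH	94
Micromonospora sp. TP-A0316	M. haikouensis JXNU-1	dDDH	74	approximate: printed as range 74-94
Micromonospora sp. TP-A0316	M. haikouensis DSM 45626	dDDH	74	approximate: printed as range 74-94
Micromonospora sp. TP-A0316	Micromonospora sp. Rc5	dDDH	74	approximate: printed as range 74-94
M. haikouensis JXNU-1	M. haikouensis DSM 45626	dDDH	74	approximate: printed as range 74-94
M. haikouensis JXNU-1	Micromonospora sp. Rc5	dDDH	74	approximate: printed as range 74-94
M. haikouensis DSM 45626	Micromonospora sp. Rc5	dDDH	74	approximate: printed as range 74-94
NRRL B-2672	M. purpureochromogenes DSM 43827	dDDH	27
M. okii TP-A0468	M. haikouensis DSM 45626	dDDH	33.5	approximate: printed as range 33.5-33.8 without per-pair attribution
M. okii TP-A0468	Micromonospora sp. TP-A0316	dDDH	33.5	approximate: printed as range 33.5-33.8 without per-pair attribution
M. okii TP-A0468	M. carbonacea DSM 43168	dDDH	33.5	approximate: printed as range 33.5-33.8 without per-pair attribution
M. okii TP-A0468	M. oryzae CP2R9-1	identity_gyrB	94.9
M. okii TP-A0468	M. carbonacea DSM 43168	identity_gyrB	94.9
M. okii TP-A0468	M. harpali NEAU-JC6	identity_gyrB	94.9
M. okii TP-A0468	M. haikouensis 232617	identity_gyrB	94.7
Micromonospora sp. TP-A0316	M. oryzae CP2R9-1	identity_gyrB	100.0
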