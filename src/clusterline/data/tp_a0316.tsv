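strain_id	cluster_id	declared_type	complete_flag	orf_id	architecture	annotation
# Cluster inventory of Micromonospora sp. TP-A0316 (arisostatin producer).
# One ORF per row; rows that the source typography ran together are stored
# with explicit separators reconstructed from the per-ORF listing
# (pks/nrps-1 ORF ids 4-217..4-247 are reconstructed from a garbled id
# column and flagged in the annotation).
TP-A0316	t1pks-1	t1pks		11-150	KS/AT/ACP-KS/AT/DH/KR/ACP-KS/AT/DH/KR/ACP-KS	arisostatins A & B, tetrocarcin A
TP-A0316	t1pks-1	t1pks		11-151	AT_mm_/DH/KR/ACP	arisostatins A & B, tetrocarcin A
TP-A0316	t1pks-1	t1pks		11-152	KS/AT_m_/DH/KR/ACP-KS/AT/DH/KR/ACP-KS/AT_m_/DH/KR/ACP-KS/AT_m_/DH/KR/ACP	arisostatins A & B, tetrocarcin A
TP-A0316	t1pks-1	t1pks		11-153	KS/AT_mm_/DH/KR/ACP	arisostatins A & B, tetrocarcin A
TP-A0316	t1pks-1	t1pks		11-154	KS/AT_m_/KR/ACP	arisostatins A & B, tetrocarcin A
TP-A0316	t1pks-1	t1pks		11-166	KS/AT/DH/ER/KR/ACP-KS/AT_mm_/DH/KR/ACP	arisostatins A & B, tetrocarcin A
TP-A0316	t1pks-2	t1pks		1-1073	CoL/KR/ACP-KS/AT_m_/DH/KR/ACP-KS/AT_mm_/DH/ER/KR/ACP	quinolidomicin congener; conserved between strains
TP-A0316	t1pks-2	t1pks		1-1077	KS/AT_m_/DH/KR/ACP	quinolidomicin congener; conserved between strains
TP-A0316	t1pks-2	t1pks		1-1078	KS/AT_m_/KR/ACP-KS/AT_m_/KR/ACP-KS/AT_m_/KR/ACP	quinolidomicin congener; conserved between strains
TP-A0316	t1pks-2	t1pks		1-1080	KS/AT_m_/DH/ER/KR/ACP-KS/AT_mm_/DH/ER/KR/ACP-KS/AT_m_/DH/ER/KR/ACP-KS/AT_m_/KR/ACP	quinolidomicin congener; conserved between strains
TP-A0316	t1pks-2	t1pks		1-1081	KS/AT_mm_/KR/ACP-KS/AT_m_/DH/KR/ACP-KS/AT_m_/DH/KR/ACP-KS/AT_m_/DH/KR/ACP-KS/AT_m_/KR/ACP-KS/AT_m_/KR/ACP	quinolidomicin congener; conserved between strains
TP-A0316	t1pks-2	t1pks		1-1091	KS/AT_m_/KR/ACP-KS/AT_mm_/DH/KR/ACP	quinolidomicin congener; conserved between strains
TP-A0316	t1pks-2	t1pks		1-1092	KS/AT_m_/DH/KR/ACP-KS/AT_mm_/KR/ACP-KS/AT_m_/KR/ACP	quinolidomicin congener; conserved between strains
TP-A0316	t1pks-2	t1pks		1-1093	KS/AT_m_/KR/ACP-KS/AT_mm_/DH/ER/KR/ACP	quinolidomicin congener; conserved between strains
TP-A0316	t1pks-2	t1pks		1-1094	KS/AT_m_/KR/ACP-KS/AT_mm_/KR/ACP-KS/AT_mm_/KR/ACP	quinolidomicin congener; conserved between strains
TP-A0316	t1pks-2	t1pks		1-1095	KS/AT_m_/DH/KR/ACP-KS/AT_mm_/DH/KR/ACP	quinolidomicin congener; conserved between strains
TP-A0316	t1pks-2	t1pks		1-1096	KS/AT_mm_/KR/ACP	quinolidomicin congener; conserved between strains
TP-A0316	t1pks-2	t1pks		1-1097	KS/AT_mm_/KR/ACP-KS/AT_m_/KR/ACP	quinolidomicin congener; conserved between strains
TP-A0316	t1pks-2	t1pks		1-1098	KS/AT_m_/ACP-Te	quinolidomicin congener; conserved between strains
TP-A0316	t1pks-3	t1pks		4-330	KS/AT/KR/DH	sporolide
TP-A0316	t1pks-4	t1pks	P	14-64	KS/AT…	unpredictable (not completely sequenced)
TP-A0316	t1pks-4	t1pks	P	16-1	…KR	unpredictable (not completely sequenced)
TP-A0316	t1pks-4	t1pks	P	16-2	KS/AT	unpredictable (not completely sequenced)
TP-A0316	t1pks-4	t1pks	P	16-3	ACP	unpredictable (not completely sequenced)
TP-A0316	t2pks-1	t2pks		4-99	KSalpha	aromatic polyketide
TP-A0316	t2pks-1	t2pks		4-100	KSbeta	aromatic polyketide
TP-A0316	t2pks-1	t2pks		4-101	ACP	aromatic polyketide
TP-A0316	t3pks-1	t3pks		2-674	KS	alkyl-O-dihydrogeranyl-methoxyhydroquinone; conserved between strains
TP-A0316	nrps-1	nrps		1-336	C/A/T-C/A_thr_/T/E	pentapeptide (x-thr-phe-ser-ile)
TP-A0316	nrps-1	nrps		1-337	C/A_phe_/T/E-C/A_ser_/T	pentapeptide (x-thr-phe-ser-ile)
TP-A0316	nrps-1	nrps		1-339	C/A_ile_/T	pentapeptide (x-thr-phe-ser-ile)
TP-A0316	nrps-2	nrps		4-510	C-C	tripeptide (x-gly-x)
TP-A0316	nrps-2	nrps		4-511	C/A/T-Te	tripeptide (x-gly-x)
TP-A0316	nrps-2	nrps		4-512	A	tripeptide (x-gly-x)
TP-A0316	nrps-2	nrps		4-513	C/A_gly_/T	tripeptide (x-gly-x)
TP-A0316	nrps-2	nrps		4-514	T	tripeptide (x-gly-x)
TP-A0316	nrps-3	nrps		6-252	C/A_cys_/T-Te	tetrapeptide (x-x-cys-cys)
TP-A0316	nrps-3	nrps		6-258	A-C/A_cys_/T	tetrapeptide (x-x-cys-cys)
TP-A0316	nrps-3	nrps		6-265	C	tetrapeptide (x-x-cys-cys)
TP-A0316	nrps-3	nrps		6-266	A	tetrapeptide (x-x-cys-cys)
TP-A0316	nrps-3	nrps		6-270	A/T	tetrapeptide (x-x-cys-cys)
TP-A0316	nrps-4	nrps	P	8-247	A/T-C	unpredictable (not completely sequenced)
TP-A0316	nrps-4	nrps	P	8-248	A/T	unpredictable (not completely sequenced)
TP-A0316	nrps-5	nrps		12-31	C/A_ser_/T-C/A_pro_/T-Te	dipeptide (ser-pro)
TP-A0316	pks/nrps-1	pks_nrps		4-217	CoL/ACP-KS/AT_m_/ACP-C/A/T-C	heptapeptide with polyketide moieties (st-pk-x-ala-glu-y-thr-ser-y); ORF ids reconstructed
TP-A0316	pks/nrps-1	pks_nrps		4-220	A_ala_/T-C	heptapeptide with polyketide moieties (st-pk-x-ala-glu-y-thr-ser-y); ORF ids reconstructed
TP-A0316	pks/nrps-1	pks_nrps		4-223	A_glu_/T-C/T	heptapeptide with polyketide moieties (st-pk-x-ala-glu-y-thr-ser-y); ORF ids reconstructed
TP-A0316	pks/nrps-1	pks_nrps		4-227	A_thr_/T	heptapeptide with polyketide moieties (st-pk-x-ala-glu-y-thr-ser-y); ORF ids reconstructed
TP-A0316	pks/nrps-1	pks_nrps		4-228	T-C	heptapeptide with polyketide moieties (st-pk-x-ala-glu-y-thr-ser-y); ORF ids reconstructed
TP-A0316	pks/nrps-1	pks_nrps		4-229	A_ser_/T-C/T-Te	heptapeptide with polyketide moieties (st-pk-x-ala-glu-y-thr-ser-y); ORF ids reconstructed
TP-A0316	pks/nrps-1	pks_nrps		4-247	A/T	heptapeptide with polyketide moieties (st-pk-x-ala-glu-y-thr-ser-y); ORF ids reconstructed
TP-A0316	pks/nrps-2	pks_nrps		6-50	C/A/T	tripeptide with polyketide moiety (ser-x-val-pk); conserved between strains
TP-A0316	pks/nrps-2	pks_nrps		6-51	KS	tripeptide with polyketide moiety (ser-x-val-pk); conserved between strains
TP-A0316	pks/nrps-2	pks_nrps		6-52	ACP	tripeptide with polyketide moiety (ser-x-val-pk); conserved between strains
TP-A0316	pks/nrps-2	pks_nrps		6-53	C/A_val_/T	tripeptide with polyketide moiety (ser-x-val-pk); conserved between strains
TP-A0316	pks/nrps-2	pks_nrps		6-54	KS/AT_m_/ACP	tripeptide with polyketide moiety (ser-x-val-pk); conserved between strains
TP-A0316	pks/nrps-2	pks_nrps		6-55	A_ser_	tripeptide with polyketide moiety (ser-x-val-pk); conserved between strains
TP-A0316	pks/nrps-3	pks_nrps		6-307	A/T-KS/DH	pentapeptide with polyketide moiety (x-pk-x-y-pk-asn-ser); conserved between strains
TP-A0316	pks/nrps-3	pks_nrps		6-310	A/T-C/T	pentapeptide with polyketide moiety (x-pk-x-y-pk-asn-ser); conserved between strains
TP-A0316	pks/nrps-3	pks_nrps		6-311	KS/AT_m_/KR/DH/ACP	pentapeptide with polyketide moiety (x-pk-x-y-pk-asn-ser); conserved between strains
TP-A0316	pks/nrps-3	pks_nrps		6-313	C/A_asn_/T	pentapeptide with polyketide moiety (x-pk-x-y-pk-asn-ser); conserved between strains
TP-A0316	pks/nrps-3	pks_nrps		6-314	C/A_ser_/T-Te	pentapeptide with polyketide moiety (x-pk-x-y-pk-asn-ser); conserved between strains
TP-A0316	pks/nrps-4	pks_nrps		8-41	A_gly_/T	hexaketide with gly
TP-A0316	pks/nrps-4	pks_nrps		8-40	KS/ACP-KS/AT_m_/DH/KR/ACP-KS/ACP-KS/KR/ACP	hexaketide with gly
TP-A0316	pks/nrps-4	pks_nrps		8-39	KS/DH/ACP-KS/AT_m_/DH/KR/ACP	hexaketide with gly
TP-A0316	pks/nrps-4	pks_nrps		8-37	AmT	hexaketide with gly
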