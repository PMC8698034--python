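strain_id	cluster_id	declared_type	complete_flag	orf_id	architecture	annotation
# Cluster inventory of Micromonospora okii TP-A0468 (kosinostatin producer).
# One ORF per row with explicit separators; the per-ORF split of rows that
# the source typography ran together is reconstructed from the matching
# reference architecture listing (t1pks-2) and from the per-ORF id lists.
# The distribution of the four rifamycin-like continuation architectures of
# t1pks-5 over ORFs 17-166..17-163 is reconstructed and approximate.
TP-A0468	t1pks-2	t1pks		8-118	CoL/ACP-KS/AT_m_/DH/KR/ACP-KS/AT_mm_/DH/ER/KR/ACP	quinolidomicin congener; conserved between strains
TP-A0468	t1pks-2	t1pks		8-122	KS/AT_m_/DH/KR/ACP	quinolidomicin congener; conserved between strains
TP-A0468	t1pks-2	t1pks		8-123	KS/AT_m_/KR/ACP-KS/AT_m_/KR/ACP-KS/AT_m_/KR/ACP	quinolidomicin congener; conserved between strains
TP-A0468	t1pks-2	t1pks		8-135	KS/AT_m_/DH/ER/KR/ACP-KS/AT/DH/ER/KR/ACP-KS/AT_m_/DH/ER/KR/ACP-KS/AT_m_/KR/ACP	quinolidomicin congener; conserved between strains
TP-A0468	t1pks-2	t1pks		8-136	KS/AT_mm_/KR/ACP	quinolidomicin congener; conserved between strains
TP-A0468	t1pks-2	t1pks		8-137	KS/AT_m_/DH/KR/ACP-KS/AT_m_/DH/KR/ACP-KS/AT_m_/DH/KR/ACP-KS/AT_m_/KR/ACP-KS/AT_m_/KR/ACP	quinolidomicin congener; conserved between strains
TP-A0468	t1pks-2	t1pks		8-146	KS/AT_m_/KR/ACP-KS/AT_mm_/DH/KR/ACP	quinolidomicin congener; conserved between strains
TP-A0468	t1pks-2	t1pks		8-147	KS/AT_m_/DH/KR/ACP-KS/KR/ACP-KS/AT_m_/KR/ACP	quinolidomicin congener; conserved between strains
TP-A0468	t1pks-2	t1pks		8-148	KS/AT/KR/ACP-KS/AT_mm_/DH/ER/KR/ACP	quinolidomicin congener; conserved between strains
TP-A0468	t1pks-2	t1pks		8-149	KS/AT_m_	quinolidomicin congener; conserved between strains
TP-A0468	t1pks-2	t1pks		8-150	KS/AT_mm_/KR/ACP-KS/AT_mm_/KR/ACP	quinolidomicin congener; conserved between strains
TP-A0468	t1pks-2	t1pks		8-151	KS/AT_m_/DH/KR/ACP-KS/AT_mm_/DH/KR/ACP	quinolidomicin congener; conserved between strains
TP-A0468	t1pks-2	t1pks		8-152	KS/AT_mm_/KR/ACP	quinolidomicin congener; conserved between strains
TP-A0468	t1pks-2	t1pks		8-153	KS/AT_mm_/KR/ACP-KS/AT_m_/KR/ACP	quinolidomicin congener; conserved between strains
TP-A0468	t1pks-2	t1pks		8-154	KS/AT_m_/ACP-Te	quinolidomicin congener; conserved between strains
TP-A0468	t1pks-5	t1pks		17-167	CoL/ACP-KS/AT_mm_/DH/KR/ACP-KS/AT_mm_/ACP-KS/AT_mm_/KR/ACP	16-demethylrifamycins
TP-A0468	t1pks-5	t1pks		17-166	KS/AT_mm_/DH/KR/ACP-KS/AT_mm_/DH/KR/ACP-KS/AT_mm_/DH/KR/ACP	16-demethylrifamycins
TP-A0468	t1pks-5	t1pks		17-165	KS/AT_mm_/DH/KR/ACP	16-demethylrifamycins
TP-A0468	t1pks-5	t1pks		17-164	KS/AT_mm_/DH/KR/ACP	16-demethylrifamycins
TP-A0468	t1pks-5	t1pks		17-163	KS/AT_m_/DH/KR/ACP-KS/AT_m_/DH/KR/ACP	16-demethylrifamycins
TP-A0468	t2pks-2	t2pks		8-66	KSalpha	kosinostatin
TP-A0468	t2pks-2	t2pks		8-67	KSbeta	kosinostatin
TP-A0468	t2pks-2	t2pks		8-68	ACP	kosinostatin
TP-A0468	t2pks-3	t2pks		15-39	KSalpha	aromatic polyketide
TP-A0468	t2pks-3	t2pks		15-40	KSbeta	aromatic polyketide
TP-A0468	t2pks-3	t2pks		15-41	ACP	aromatic polyketide
TP-A0468	t3pks-1	t3pks		13-182	KS	alkyl-O-dihydrogeranyl-methoxyhydroquinone; conserved between strains
TP-A0468	t3pks-2	t3pks		9-577	KS	polyketide with guanidinotide moiety
TP-A0468	nrps-6	nrps	P	8-1	…T	pyochelin (not completely sequenced)
TP-A0468	nrps-6	nrps	P	8-2	C/A_cys_/MT/T	pyochelin (not completely sequenced)
TP-A0468	nrps-6	nrps	P	8-14	A_dhb_	pyochelin (not completely sequenced)
TP-A0468	nrps-7	nrps		9-387	A_glu_/T-TD	glu with beta-lactone
TP-A0468	nrps-8	nrps		16-60	T	dipeptide (val-pro)
TP-A0468	nrps-8	nrps		16-59	A_val_	dipeptide (val-pro)
TP-A0468	nrps-8	nrps		16-58	C/A_pro_/T-TD	dipeptide (val-pro)
TP-A0468	nrps-9	nrps		19-118	A/T	dipeptide (x-x)
TP-A0468	nrps-9	nrps		19-110	C/A/T	dipeptide (x-x)
TP-A0468	nrps-10	nrps		20-72	A	dipeptide (x-x)
TP-A0468	nrps-10	nrps		20-83	A/T/E	dipeptide (x-x)
TP-A0468	pks/nrps-2	pks_nrps		24-73	C/A/T	tripeptide with polyketide moiety (ser-x-val-pk); conserved between strains
TP-A0468	pks/nrps-2	pks_nrps		24-74	KS	tripeptide with polyketide moiety (ser-x-val-pk); conserved between strains
TP-A0468	pks/nrps-2	pks_nrps		24-75	ACP	tripeptide with polyketide moiety (ser-x-val-pk); conserved between strains
TP-A0468	pks/nrps-2	pks_nrps		24-76	C/A_val_/T	tripeptide with polyketide moiety (ser-x-val-pk); conserved between strains
TP-A0468	pks/nrps-2	pks_nrps		24-77	KS/AT_m_/ACP	tripeptide with polyketide moiety (ser-x-val-pk); conserved between strains
TP-A0468	pks/nrps-2	pks_nrps		24-78	A_ser_	tripeptide with polyketide moiety (ser-x-val-pk); conserved between strains
TP-A0468	pks/nrps-3	pks_nrps		17-59	A/T-KS/DH	pentapeptide with polyketide moiety (x-pk-x-y-pk-asn-ser); conserved between strains
TP-A0468	pks/nrps-3	pks_nrps		17-56	A/T-C/T	pentapeptide with polyketide moiety (x-pk-x-y-pk-asn-ser); conserved between strains
TP-A0468	pks/nrps-3	pks_nrps		17-55	KS/AT_m_/KR/DH/ACP	pentapeptide with polyketide moiety (x-pk-x-y-pk-asn-ser); conserved between strains
TP-A0468	pks/nrps-3	pks_nrps		17-52	C/A_asn_/T	pentapeptide with polyketide moiety (x-pk-x-y-pk-asn-ser); conserved between strains
TP-A0468	pks/nrps-3	pks_nrps		17-51	C/A_ser_/T-Te	pentapeptide with polyketide moiety (x-pk-x-y-pk-asn-ser); conserved between strains
TP-A0468	pks/nrps-5	pks_nrps		21-43	C/A_asn_/T-C/A/T	methyltallysomycin
TP-A0468	pks/nrps-5	pks_nrps		21-44	C/A_ser_/T	methyltallysomycin
TP-A0468	pks/nrps-5	pks_nrps		21-45	KS/AT_m_/MT/KR/ACP	methyltallysomycin
TP-A0468	pks/nrps-5	pks_nrps		21-46	C/A/T	methyltallysomycin
TP-A0468	pks/nrps-5	pks_nrps		21-47	CoL/T-C/A_ser_/T-C	methyltallysomycin
TP-A0468	pks/nrps-5	pks_nrps		21-48	T-C	methyltallysomycin
TP-A0468	pks/nrps-5	pks_nrps		21-50	C/A_b-ala_/T-C/A_cys_/T-C	methyltallysomycin
TP-A0468	pks/nrps-5	pks_nrps		21-51	A/T	methyltallysomycin
TP-A0468	pks/nrps-5	pks_nrps		21-53	C	methyltallysomycin
TP-A0468	pks/nrps-5	pks_nrps		21-62	A/T	methyltallysomycin
TP-A0468	pks/nrps-6	pks_nrps		26-56	A/T-KS/AT_m_/ACP-C/A/T-C	dipeptide with polyketide moiety (x-pk-x)
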