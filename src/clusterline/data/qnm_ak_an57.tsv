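strain_id	cluster_id	declared_type	complete_flag	orf_id	architecture	annotation
# Quinolidomicin assembly line (qnm) of Micromonospora chalcea AK-AN57:
# the reference column of the module-by-module comparison table.
# 34 assembly-line positions: loading module L plus extension modules 1-33.
AK-AN57	qnm	t1pks		qnmA1	CoL/ACP-KS/AT_m_/DH/KR/ACP-KS/AT_mm_/DH/ER/KR/ACP	quinolidomicin A1
AK-AN57	qnm	t1pks		qnmA2	KS/AT_m_/DH/KR/ACP	quinolidomicin A1
AK-AN57	qnm	t1pks		qnmA3	KS/AT_m_/DH/KR/ACP-KS/AT_m_/KR/ACP-KS/AT_m_/KR/ACP-KS/AT_m_/KR/ACP	quinolidomicin A1
AK-AN57	qnm	t1pks		qnmA4	KS/AT_m_/DH/ER/KR/ACP-KS/AT/DH/ER/KR/ACP-KS/AT_m_/DH/KR/ACP-KS/AT_m_/KR/ACP	quinolidomicin A1
AK-AN57	qnm	t1pks		qnmA5	KS/AT_m_/KR/ACP-KS/AT_m_/DH/KR/ACP-KS/AT_m_/DH/KR/ACP-KS/AT_m_/DH/KR/ACP-KS/AT_m_/KR/ACP-KS/AT_m_/KR/ACP	quinolidomicin A1
AK-AN57	qnm	t1pks		qnmA6	KS/AT_m_/KR/ACP-KS/DH/KR/ACP	quinolidomicin A1
AK-AN57	qnm	t1pks		qnmA7	KS/AT_m_/DH/KR/ACP-KS/AT_mm_/KR/ACP-KS/AT_m_/KR/ACP	quinolidomicin A1
AK-AN57	qnm	t1pks		qnmA8	KS/AT_m_/KR/ACP-KS/AT_mm_/DH/ER/KR/ACP	quinolidomicin A1
AK-AN57	qnm	t1pks		qnmA9	KS/AT_m_/KR/ACP-KS/AT_mm_/KR/ACP-KS/AT_mm_/KR/ACP	quinolidomicin A1
AK-AN57	qnm	t1pks		qnmA10	KS/AT_m_/DH/KR/ACP-KS/AT_mm_/DH/KR/ACP	quinolidomicin A1
AK-AN57	qnm	t1pks		qnmA11	KS/AT_mm_/KR/ACP	quinolidomicin A1
AK-AN57	qnm	t1pks		qnmA12	KS/AT_mm_/KR/ACP-KS/AT_m_/KR/ACP	quinolidomicin A1
AK-AN57	qnm	t1pks		qnmA13	KS/AT_m_/KR/ACP/Te	quinolidomicin A1
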