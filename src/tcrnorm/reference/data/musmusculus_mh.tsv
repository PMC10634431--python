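# Mouse MH gene registry: IMGT MH1-/MH2- nomenclature with legacy H2 synonyms.
# Columns: symbol, locus, chain, mh_class, alleles, synonyms.
# Haplotype-qualified legacy names (H2-Kb, H2-Db, ...) are synonyms of the
# haplotype-free IMGT gene; the H2-/H-2 prefix itself is also handled by a
# rewrite in the standardizer, so only letter-qualified forms need rows here.
symbol	locus	chain	mh_class	alleles	synonyms
MH1-D1	MH	alpha	1	-	H2-D|H2-DB|H2-DD|H2-DK
MH1-K1	MH	alpha	1	-	H2-K|H2-KB|H2-KD|H2-KK
MH1-L	MH	alpha	1	-	H2-LD
MH1-Q1	MH	alpha	1	-	-
MH1-Q2	MH	alpha	1	-	-
MH1-Q3	MH	alpha	1	-	-
MH1-Q4	MH	alpha	1	-	-
MH1-Q5	MH	alpha	1	-	-
MH1-Q6	MH	alpha	1	-	-
MH1-Q7	MH	alpha	1	-	-
MH1-Q8	MH	alpha	1	-	-
MH1-Q9	MH	alpha	1	-	-
MH1-Q10	MH	alpha	1	-	-
MH1-M1	MH	alpha	1	-	-
MH1-M2	MH	alpha	1	-	-
MH1-M3	MH	alpha	1	-	-
MH1-M4	MH	alpha	1	-	-
MH1-M5	MH	alpha	1	-	CRW2
MH1-M6	MH	alpha	1	-	-
MH1-T3	MH	alpha	1	-	-
MH1-T9	MH	alpha	1	-	-
MH1-T10	MH	alpha	1	-	-
MH1-T22	MH	alpha	1	-	-
MH1-T23	MH	alpha	1	-	-
B2M	MH	beta	1	-	-
MH2-AA	MH	alpha	2	-	H2-IAA
MH2-AB1	MH	beta	2	-	H2-IAB
MH2-EA	MH	alpha	2	-	H2-IEA
MH2-EB1	MH	beta	2	-	H2-IEB
MH2-EB2	MH	beta	2	-	-
MH2-OA	MH	alpha	2	-	-
MH2-OB	MH	beta	2	-	-
MH2-DMA	MH	alpha	2	-	-
MH2-DMB1	MH	beta	2	-	-
MH2-DMB2	MH	beta	2	-	-
MH2-PA	MH	alpha	2	-	-
MH2-PB	MH	beta	2	-	-
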