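# Human MH (HLA) gene registry: classical class I and II genes plus B2M.
# Columns: symbol, locus, chain, mh_class, alleles, synonyms.
# Allele designations for HLA genes are not catalogued here (the allele
# catalogue is four orders of magnitude larger than the gene list); the
# standardizer validates the root and keeps zero-padded allele fields as given.
# Non-classical MH (MR1, CD1, MIC) are deliberately absent: they are not
# supported and must fail standardization.
symbol	locus	chain	mh_class	alleles	synonyms
HLA-A	MH	alpha	1	-	-
HLA-B	MH	alpha	1	-	-
HLA-C	MH	alpha	1	-	-
HLA-E	MH	alpha	1	-	-
HLA-F	MH	alpha	1	-	-
HLA-G	MH	alpha	1	-	-
B2M	MH	beta	1	-	-
HLA-DRA	MH	alpha	2	-	-
HLA-DRB1	MH	beta	2	-	-
HLA-DRB3	MH	beta	2	-	-
HLA-DRB4	MH	beta	2	-	-
HLA-DRB5	MH	beta	2	-	-
HLA-DQA1	MH	alpha	2	-	-
HLA-DQA2	MH	alpha	2	-	-
HLA-DQB1	MH	beta	2	-	-
HLA-DQB2	MH	beta	2	-	-
HLA-DPA1	MH	alpha	2	-	-
HLA-DPA2	MH	alpha	2	-	-
HLA-DPB1	MH	beta	2	-	-
HLA-DPB2	MH	beta	2	-	-
HLA-DMA	MH	alpha	2	-	-
HLA-DMB	MH	beta	2	-	-
HLA-DOA	MH	alpha	2	-	-
HLA-DOB	MH	beta	2	-	-
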