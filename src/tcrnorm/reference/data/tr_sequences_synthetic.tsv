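# SYNTHETIC per-gene amino-acid feature sequences for the TR sequence-lookup
# utility. These are placeholder sequences generated for testing the lookup
# machinery; they are NOT IMGT germline sequences and must not be used for
# biological inference. Coverage is deliberately partial so the "no sequence
# data" error path stays reachable.
# Columns: species, symbol, feature, sequence.
species	symbol	feature	sequence
homosapiens	TRBV6-4	CDR1-IMGT	SGHDY
homosapiens	TRBV6-4	CDR2-IMGT	FNNNVP
homosapiens	TRBV6-4	FR3-IMGT	IDDSGMPEDRFSAKMPNASFSTLKIQPSEPRDSAVYF
homosapiens	TRBV5-1	CDR1-IMGT	SGHRS
homosapiens	TRBV5-1	CDR2-IMGT	YFSETQ
homosapiens	TRBV5-1	FR3-IMGT	EKGDIPEGYKVSRKEKRNFPLILESPSPNQTSLYF
homosapiens	TRAV1-1	CDR1-IMGT	TSGFNG
homosapiens	TRAV1-1	CDR2-IMGT	NVLDGL
homosapiens	TRAJ1	FR4-IMGT	NYGQNFVF
musmusculus	TRBV2	CDR1-IMGT	NSQYPW
musmusculus	TRBV2	CDR2-IMGT	LRSPGD
musmusculus	TRAV14D-3/DV8	CDR1-IMGT	TSSGTY
musmusculus	TRAV14D-3/DV8	CDR2-IMGT	GLKNN
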