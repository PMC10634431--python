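# Mouse T cell receptor gene registry (IMGT gene-level list, curated).
# Columns: symbol, locus, chain, mh_class, alleles (designation=functionality, |-sep), synonyms (|-sep).
# Synonyms cover legacy Arden-style V-beta numbering exercised in practice, whose
# subfamily numbers do not coincide with IMGT gene numbers (e.g. Vb22 -> TRBV2).
symbol	locus	chain	mh_class	alleles	synonyms
TRAV1	TR	-	-	01=F|02=F	-
TRAV2	TR	-	-	01=F	-
TRAV3-1	TR	-	-	01=F|02=F	-
TRAV3-3	TR	-	-	01=F	-
TRAV3-4	TR	-	-	01=F	-
TRAV3D-3	TR	-	-	01=F|02=F	-
TRAV4-2	TR	-	-	01=F	-
TRAV4-3	TR	-	-	01=F	-
TRAV4-4/DV10	TR	-	-	01=F|02=F	-
TRAV4D-3	TR	-	-	01=F	-
TRAV4D-4	TR	-	-	01=F|02=F	-
TRAV5-1	TR	-	-	01=F	-
TRAV5-2	TR	-	-	01=F	-
TRAV5-4	TR	-	-	01=F	-
TRAV5D-4	TR	-	-	01=F|02=F	-
TRAV6-1	TR	-	-	01=F	-
TRAV6-2	TR	-	-	01=F	-
TRAV6-3	TR	-	-	01=F|02=F	-
TRAV6-4	TR	-	-	01=F	-
TRAV6-5	TR	-	-	01=F	-
TRAV6-6	TR	-	-	01=F	-
TRAV6-7/DV9	TR	-	-	01=F|02=F	-
TRAV6D-3	TR	-	-	01=F	-
TRAV6D-4	TR	-	-	01=F	-
TRAV6D-5	TR	-	-	01=F	-
TRAV6D-6	TR	-	-	01=F	-
TRAV6D-7	TR	-	-	01=F|02=F	-
TRAV7-1	TR	-	-	01=F	-
TRAV7-2	TR	-	-	01=F	-
TRAV7-3	TR	-	-	01=F|02=F	-
TRAV7-4	TR	-	-	01=F	-
TRAV7-5	TR	-	-	01=F	-
TRAV7-6	TR	-	-	01=F	-
TRAV7D-2	TR	-	-	01=F|02=F	-
TRAV7D-3	TR	-	-	01=F	-
TRAV7D-4	TR	-	-	01=F	-
TRAV7D-5	TR	-	-	01=F	-
TRAV7D-6	TR	-	-	01=F	-
TRAV8-1	TR	-	-	01=F	-
TRAV8-2	TR	-	-	01=F	-
TRAV8D-1	TR	-	-	01=F|02=F	-
TRAV8D-2	TR	-	-	01=F|02=F	-
TRAV9-1	TR	-	-	01=F	-
TRAV9-2	TR	-	-	01=F	-
TRAV9-3	TR	-	-	01=F	-
TRAV9-4	TR	-	-	01=F	-
TRAV9D-1	TR	-	-	01=F	-
TRAV9D-2	TR	-	-	01=F	-
TRAV9D-3	TR	-	-	01=F	-
TRAV9D-4	TR	-	-	01=F|02=F	-
TRAV10	TR	-	-	01=F	-
TRAV10D	TR	-	-	01=F	-
TRAV11	TR	-	-	01=F	-
TRAV11D	TR	-	-	01=F	-
TRAV12-1	TR	-	-	01=F	-
TRAV12-2	TR	-	-	01=F	-
TRAV12-3	TR	-	-	01=F	-
TRAV12D-1	TR	-	-	01=F	-
TRAV12D-2	TR	-	-	01=F|02=F	-
TRAV12D-3	TR	-	-	01=F	-
TRAV13-1	TR	-	-	01=F	-
TRAV13-2	TR	-	-	01=F	-
TRAV13-3	TR	-	-	01=F	-
TRAV13-4/DV7	TR	-	-	01=F|02=F	-
TRAV13-5	TR	-	-	01=F	-
TRAV13D-1	TR	-	-	01=F	-
TRAV13D-2	TR	-	-	01=F	-
TRAV13D-3	TR	-	-	01=F	-
TRAV13D-4	TR	-	-	01=F	-
TRAV14-1	TR	-	-	01=F	-
TRAV14-2	TR	-	-	01=F	-
TRAV14-3	TR	-	-	01=F	-
TRAV14D-1	TR	-	-	01=F	-
TRAV14D-2	TR	-	-	01=F	-
TRAV14D-3/DV8	TR	-	-	01=F|02=F	-
TRAV15-1/DV6-1	TR	-	-	01=F|02=F	-
TRAV15-2/DV6-2	TR	-	-	01=F|02=F	-
TRAV15D-1/DV6D-1	TR	-	-	01=F	-
TRAV15D-2/DV6D-2	TR	-	-	01=F	-
TRAV16	TR	-	-	01=F	-
TRAV16D/DV11	TR	-	-	01=F|02=F	-
TRAV17	TR	-	-	01=F	-
TRAV18	TR	-	-	01=P	-
TRAV19	TR	-	-	01=F	-
TRAV20	TR	-	-	01=F	-
TRAV21/DV12	TR	-	-	01=F|02=F	-
TRAJ2	TR	-	-	01=F	-
TRAJ4	TR	-	-	01=ORF	-
TRAJ5	TR	-	-	01=F	-
TRAJ6	TR	-	-	01=F	-
TRAJ7	TR	-	-	01=ORF	-
TRAJ9	TR	-	-	01=F	-
TRAJ11	TR	-	-	01=F	-
TRAJ12	TR	-	-	01=F	-
TRAJ13	TR	-	-	01=F	-
TRAJ15	TR	-	-	01=F	-
TRAJ16	TR	-	-	01=F	-
TRAJ17	TR	-	-	01=F	-
TRAJ18	TR	-	-	01=F	-
TRAJ19	TR	-	-	01=P	-
TRAJ21	TR	-	-	01=F	-
TRAJ22	TR	-	-	01=F	-
TRAJ23	TR	-	-	01=F	-
TRAJ24	TR	-	-	01=F	-
TRAJ26	TR	-	-	01=F	-
TRAJ27	TR	-	-	01=F	-
TRAJ28	TR	-	-	01=F	-
TRAJ30	TR	-	-	01=F	-
TRAJ31	TR	-	-	01=F	-
TRAJ32	TR	-	-	01=F	-
TRAJ33	TR	-	-	01=F	-
TRAJ34	TR	-	-	01=F	-
TRAJ35	TR	-	-	01=F	-
TRAJ37	TR	-	-	01=F	-
TRAJ38	TR	-	-	01=F	-
TRAJ39	TR	-	-	01=F	-
TRAJ40	TR	-	-	01=F	-
TRAJ42	TR	-	-	01=F	-
TRAJ43	TR	-	-	01=F	-
TRAJ44	TR	-	-	01=F	-
TRAJ45	TR	-	-	01=F	-
TRAJ46	TR	-	-	01=F	-
TRAJ47	TR	-	-	01=F	-
TRAJ48	TR	-	-	01=F	-
TRAJ49	TR	-	-	01=F	-
TRAJ50	TR	-	-	01=F	-
TRAJ52	TR	-	-	01=F	-
TRAJ53	TR	-	-	01=F	-
TRAJ56	TR	-	-	01=F	-
TRAJ57	TR	-	-	01=F	-
TRAJ58	TR	-	-	01=F	-
TRBV1	TR	-	-	01=F|02=F	-
TRBV2	TR	-	-	01=F|02=F	TRBV22S1
TRBV3	TR	-	-	01=F	-
TRBV4	TR	-	-	01=F|02=F	-
TRBV5	TR	-	-	01=F|02=F	-
TRBV12-1	TR	-	-	01=F	-
TRBV12-2	TR	-	-	01=F	-
TRBV13-1	TR	-	-	01=F|02=F	TRBV8S3
TRBV13-2	TR	-	-	01=F|02=F	TRBV8S2
TRBV13-3	TR	-	-	01=F|02=F	TRBV8S1
TRBV14	TR	-	-	01=F	-
TRBV15	TR	-	-	01=F	-
TRBV16	TR	-	-	01=F	-
TRBV17	TR	-	-	01=F	-
TRBV19	TR	-	-	01=F|02=F	-
TRBV20	TR	-	-	01=F	-
TRBV21	TR	-	-	01=P	-
TRBV23	TR	-	-	01=ORF	-
TRBV24	TR	-	-	01=ORF	-
TRBV26	TR	-	-	01=F	-
TRBV29	TR	-	-	01=F|02=F	-
TRBV30	TR	-	-	01=F	-
TRBV31	TR	-	-	01=F|02=F	-
TRBD1	TR	-	-	01=F	-
TRBD2	TR	-	-	01=F	-
TRBJ1-1	TR	-	-	01=F	-
TRBJ1-2	TR	-	-	01=F	-
TRBJ1-3	TR	-	-	01=F	-
TRBJ1-4	TR	-	-	01=F	-
TRBJ1-5	TR	-	-	01=F	-
TRBJ1-6	TR	-	-	01=ORF	-
TRBJ1-7	TR	-	-	01=P	-
TRBJ2-1	TR	-	-	01=F	-
TRBJ2-2	TR	-	-	01=F	-
TRBJ2-3	TR	-	-	01=F	-
TRBJ2-4	TR	-	-	01=F	-
TRBJ2-5	TR	-	-	01=F	-
TRBJ2-6	TR	-	-	01=P	-
TRBJ2-7	TR	-	-	01=F	-
TRGV1	TR	-	-	01=F	-
TRGV2	TR	-	-	01=F	-
TRGV3	TR	-	-	01=P	-
TRGV4	TR	-	-	01=F	-
TRGV5	TR	-	-	01=F	-
TRGV6	TR	-	-	01=F	-
TRGV7	TR	-	-	01=F	-
TRGJ1	TR	-	-	01=F	-
TRGJ2	TR	-	-	01=P	-
TRGJ3	TR	-	-	01=ORF	-
TRGJ4	TR	-	-	01=F	-
TRDV1	TR	-	-	01=F	-
TRDV2-1	TR	-	-	01=F	-
TRDV2-2	TR	-	-	01=F|02=F	-
TRDV4	TR	-	-	01=F	-
TRDV5	TR	-	-	01=F	-
TRDD1	TR	-	-	01=F	-
TRDD2	TR	-	-	01=F	-
TRDJ1	TR	-	-	01=F	-
TRDJ2	TR	-	-	01=F	-
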