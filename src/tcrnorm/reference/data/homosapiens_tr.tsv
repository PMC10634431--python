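# Human T cell receptor gene registry (IMGT gene-level list, curated).
# Columns: symbol, locus, chain, mh_class, alleles (designation=functionality, |-sep), synonyms (|-sep).
# '-' means empty. Functionality classes: F functional, ORF open reading frame, P pseudogene.
symbol	locus	chain	mh_class	alleles	synonyms
TRAV1-1	TR	-	-	01=F|02=F	-
TRAV1-2	TR	-	-	01=F|02=F	-
TRAV2	TR	-	-	01=F|02=F	-
TRAV3	TR	-	-	01=F|02=F	-
TRAV4	TR	-	-	01=F|02=F	-
TRAV5	TR	-	-	01=F	-
TRAV6	TR	-	-	01=F|02=F	-
TRAV7	TR	-	-	01=F	-
TRAV8-1	TR	-	-	01=F|02=F	-
TRAV8-2	TR	-	-	01=F|02=F	-
TRAV8-3	TR	-	-	01=F|02=F	-
TRAV8-4	TR	-	-	01=F|02=F	-
TRAV8-5	TR	-	-	01=P	-
TRAV8-6	TR	-	-	01=F|02=F	-
TRAV8-7	TR	-	-	01=ORF	-
TRAV9-1	TR	-	-	01=F	-
TRAV9-2	TR	-	-	01=F|02=F	-
TRAV10	TR	-	-	01=F	-
TRAV11	TR	-	-	01=P	-
TRAV12-1	TR	-	-	01=F|02=F	-
TRAV12-2	TR	-	-	01=F|02=F	-
TRAV12-3	TR	-	-	01=F|02=F	-
TRAV13-1	TR	-	-	01=F|02=F	-
TRAV13-2	TR	-	-	01=F|02=F	-
TRAV14/DV4	TR	-	-	01=F|02=F	-
TRAV15	TR	-	-	01=P	-
TRAV16	TR	-	-	01=F	-
TRAV17	TR	-	-	01=F	-
TRAV18	TR	-	-	01=F	-
TRAV19	TR	-	-	01=F	-
TRAV20	TR	-	-	01=F|02=F	-
TRAV21	TR	-	-	01=F|02=F	-
TRAV22	TR	-	-	01=F	-
TRAV23/DV6	TR	-	-	01=F|02=F	-
TRAV24	TR	-	-	01=F	-
TRAV25	TR	-	-	01=F	-
TRAV26-1	TR	-	-	01=F|02=F	-
TRAV26-2	TR	-	-	01=F|02=F	-
TRAV27	TR	-	-	01=F|02=F	-
TRAV28	TR	-	-	01=P	-
TRAV29/DV5	TR	-	-	01=F|02=F	-
TRAV30	TR	-	-	01=F|02=F	-
TRAV31	TR	-	-	01=P	-
TRAV32	TR	-	-	01=P	-
TRAV33	TR	-	-	01=P	-
TRAV34	TR	-	-	01=F	-
TRAV35	TR	-	-	01=F|02=F	-
TRAV36/DV7	TR	-	-	01=F|02=F	-
TRAV37	TR	-	-	01=P	-
TRAV38-1	TR	-	-	01=F|02=F	-
TRAV38-2/DV8	TR	-	-	01=F	-
TRAV39	TR	-	-	01=F	-
TRAV40	TR	-	-	01=F	-
TRAV41	TR	-	-	01=F	-
TRAJ1	TR	-	-	01=ORF	-
TRAJ2	TR	-	-	01=ORF	-
TRAJ3	TR	-	-	01=F	-
TRAJ4	TR	-	-	01=F	-
TRAJ5	TR	-	-	01=F	-
TRAJ6	TR	-	-	01=F	-
TRAJ7	TR	-	-	01=F	-
TRAJ8	TR	-	-	01=F	-
TRAJ9	TR	-	-	01=F	-
TRAJ10	TR	-	-	01=F	-
TRAJ11	TR	-	-	01=F	-
TRAJ12	TR	-	-	01=F	-
TRAJ13	TR	-	-	01=F|02=F	-
TRAJ14	TR	-	-	01=F	-
TRAJ15	TR	-	-	01=F|02=F	-
TRAJ16	TR	-	-	01=F	-
TRAJ17	TR	-	-	01=F	-
TRAJ18	TR	-	-	01=F	-
TRAJ19	TR	-	-	01=ORF	-
TRAJ20	TR	-	-	01=F	-
TRAJ21	TR	-	-	01=F	-
TRAJ22	TR	-	-	01=F	-
TRAJ23	TR	-	-	01=F	-
TRAJ24	TR	-	-	01=F|02=F	-
TRAJ25	TR	-	-	01=ORF	-
TRAJ26	TR	-	-	01=F	-
TRAJ27	TR	-	-	01=F	-
TRAJ28	TR	-	-	01=F	-
TRAJ29	TR	-	-	01=F	-
TRAJ30	TR	-	-	01=F	-
TRAJ31	TR	-	-	01=F	-
TRAJ32	TR	-	-	01=F|02=F	-
TRAJ33	TR	-	-	01=F	-
TRAJ34	TR	-	-	01=F	-
TRAJ35	TR	-	-	01=ORF	-
TRAJ36	TR	-	-	01=F	-
TRAJ37	TR	-	-	01=F|02=F	-
TRAJ38	TR	-	-	01=F	-
TRAJ39	TR	-	-	01=F	-
TRAJ40	TR	-	-	01=F	-
TRAJ41	TR	-	-	01=F	-
TRAJ42	TR	-	-	01=F	-
TRAJ43	TR	-	-	01=F	-
TRAJ44	TR	-	-	01=F	-
TRAJ45	TR	-	-	01=F	-
TRAJ46	TR	-	-	01=F	-
TRAJ47	TR	-	-	01=F|02=F	-
TRAJ48	TR	-	-	01=F	-
TRAJ49	TR	-	-	01=F	-
TRAJ50	TR	-	-	01=F	-
TRAJ51	TR	-	-	01=P	-
TRAJ52	TR	-	-	01=F	-
TRAJ53	TR	-	-	01=F	-
TRAJ54	TR	-	-	01=F	-
TRAJ55	TR	-	-	01=P	-
TRAJ56	TR	-	-	01=F	-
TRAJ57	TR	-	-	01=F	-
TRAJ58	TR	-	-	01=ORF	-
TRAJ59	TR	-	-	01=ORF	-
TRAJ60	TR	-	-	01=P	-
TRAJ61	TR	-	-	01=P	-
TRBV1	TR	-	-	01=P	-
TRBV2	TR	-	-	01=F|02=F	-
TRBV3-1	TR	-	-	01=F|02=F	-
TRBV3-2	TR	-	-	01=P	-
TRBV4-1	TR	-	-	01=F|02=F	-
TRBV4-2	TR	-	-	01=F|02=F	-
TRBV4-3	TR	-	-	01=F|02=F	-
TRBV5-1	TR	-	-	01=F|02=F	-
TRBV5-2	TR	-	-	01=P	-
TRBV5-3	TR	-	-	01=ORF	-
TRBV5-4	TR	-	-	01=F|02=F	-
TRBV5-5	TR	-	-	01=F|02=F	-
TRBV5-6	TR	-	-	01=F	-
TRBV5-7	TR	-	-	01=ORF	-
TRBV5-8	TR	-	-	01=F|02=F	-
TRBV6-1	TR	-	-	01=F	-
TRBV6-2	TR	-	-	01=F	-
TRBV6-3	TR	-	-	01=F	-
TRBV6-4	TR	-	-	01=F|02=F	-
TRBV6-5	TR	-	-	01=F	-
TRBV6-6	TR	-	-	01=F|02=F	-
TRBV6-7	TR	-	-	01=ORF	-
TRBV6-8	TR	-	-	01=F	-
TRBV6-9	TR	-	-	01=F	-
TRBV7-1	TR	-	-	01=P	-
TRBV7-2	TR	-	-	01=F|02=F	-
TRBV7-3	TR	-	-	01=F|02=F	-
TRBV7-4	TR	-	-	01=F	-
TRBV7-5	TR	-	-	01=P	-
TRBV7-6	TR	-	-	01=F|02=F	-
TRBV7-7	TR	-	-	01=F|02=F	-
TRBV7-8	TR	-	-	01=F|02=F	-
TRBV7-9	TR	-	-	01=F|02=F	-
TRBV8-1	TR	-	-	01=P	-
TRBV8-2	TR	-	-	01=P	-
TRBV9	TR	-	-	01=F|02=F	-
TRBV10-1	TR	-	-	01=F|02=F	-
TRBV10-2	TR	-	-	01=F|02=F	-
TRBV10-3	TR	-	-	01=F|02=F	-
TRBV11-1	TR	-	-	01=F	-
TRBV11-2	TR	-	-	01=F|02=F	-
TRBV11-3	TR	-	-	01=F|02=F	-
TRBV12-1	TR	-	-	01=P	-
TRBV12-2	TR	-	-	01=P	-
TRBV12-3	TR	-	-	01=F	-
TRBV12-4	TR	-	-	01=F|02=F	-
TRBV12-5	TR	-	-	01=F	-
TRBV13	TR	-	-	01=F|02=F	-
TRBV14	TR	-	-	01=F|02=F	-
TRBV15	TR	-	-	01=F|02=F	-
TRBV16	TR	-	-	01=F|02=F	-
TRBV17	TR	-	-	01=ORF|02=ORF	-
TRBV18	TR	-	-	01=F	-
TRBV19	TR	-	-	01=F|02=F	-
TRBV20-1	TR	-	-	01=F|02=F	-
TRBV21-1	TR	-	-	01=P	-
TRBV22-1	TR	-	-	01=P	-
TRBV23-1	TR	-	-	01=ORF	-
TRBV24-1	TR	-	-	01=F|02=F	-
TRBV25-1	TR	-	-	01=F|02=F	-
TRBV26	TR	-	-	01=P	-
TRBV27	TR	-	-	01=F|02=F	-
TRBV28	TR	-	-	01=F	-
TRBV29-1	TR	-	-	01=F|02=F	-
TRBV30	TR	-	-	01=F|02=F	-
TRBD1	TR	-	-	01=F	-
TRBD2	TR	-	-	01=F|02=F	-
TRBJ1-1	TR	-	-	01=F	-
TRBJ1-2	TR	-	-	01=F	-
TRBJ1-3	TR	-	-	01=F	-
TRBJ1-4	TR	-	-	01=F	-
TRBJ1-5	TR	-	-	01=F	-
TRBJ1-6	TR	-	-	01=F|02=F	-
TRBJ2-1	TR	-	-	01=F	-
TRBJ2-2	TR	-	-	01=F	-
TRBJ2-2P	TR	-	-	01=ORF	-
TRBJ2-3	TR	-	-	01=F	-
TRBJ2-4	TR	-	-	01=F	-
TRBJ2-5	TR	-	-	01=F	-
TRBJ2-6	TR	-	-	01=F	-
TRBJ2-7	TR	-	-	01=F|02=F	-
TRGV1	TR	-	-	01=P	-
TRGV2	TR	-	-	01=F|02=F	-
TRGV3	TR	-	-	01=F|02=F	-
TRGV4	TR	-	-	01=F|02=F	-
TRGV5	TR	-	-	01=F|02=F	-
TRGV5P	TR	-	-	01=P	-
TRGV6	TR	-	-	01=P	-
TRGV7	TR	-	-	01=P	-
TRGV8	TR	-	-	01=F	-
TRGV9	TR	-	-	01=F|02=F	-
TRGV10	TR	-	-	01=ORF	-
TRGV11	TR	-	-	01=ORF	-
TRGJ1	TR	-	-	01=F|02=F	-
TRGJ2	TR	-	-	01=F	-
TRGJP	TR	-	-	01=F	-
TRGJP1	TR	-	-	01=F	-
TRGJP2	TR	-	-	01=F	-
TRDV1	TR	-	-	01=F	-
TRDV2	TR	-	-	01=F|02=F	-
TRDV3	TR	-	-	01=F	-
TRDD1	TR	-	-	01=F	-
TRDD2	TR	-	-	01=F	-
TRDD3	TR	-	-	01=F	-
TRDJ1	TR	-	-	01=F	-
TRDJ2	TR	-	-	01=F	-
TRDJ3	TR	-	-	01=F	-
TRDJ4	TR	-	-	01=F	-
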