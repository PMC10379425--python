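# Palaemon tenuidactylus complete mitogenome annotation (GenBank OP650931),
# transcribed from the published annotation table of the deposited record.
# genome_length=15735  organism=Palaemon tenuidactylus  accession=OP650931
# Coordinates 1-based inclusive; intergenic = signed gap to the next feature
# ("." on the CR row, the published table's convention); negative = overlap.
symbol	strand	start	end	size	intergenic	start_codon	stop_codon	anticodon
cox1	+	1	1535	1535	0	ATG	T(AA)	.
trnL2	+	1536	1600	65	2	.	.	TAA
cox2	+	1603	2290	688	3	ATG	T(AA)	.
trnK	+	2294	2359	66	4	.	.	TTT
trnD	+	2364	2424	61	2	.	.	GTC
atp8	+	2427	2585	159	-7	ATC	TAA	.
atp6	+	2579	3253	675	-1	ATG	TAA	.
cox3	+	3253	4041	789	3	ATG	TAA	.
trnG	+	4045	4108	64	0	.	.	TCC
nad3	+	4109	4462	354	4	ATT	TAA	.
trnA	+	4467	4529	63	-1	.	.	TGC
trnR	+	4529	4594	66	3	.	.	TCG
trnN	+	4598	4661	64	-1	.	.	GTT
trnS1	+	4661	4727	67	0	.	.	TCT
trnE	+	4728	4795	68	-2	.	.	TTC
trnF	-	4794	4857	64	0	.	.	GAA
nad5	-	4858	6570	1713	12	ATT	TAA	.
trnH	-	6583	6644	62	0	.	.	GTG
nad4	-	6645	7979	1335	-7	ATG	TAA	.
nad4l	-	7973	8272	300	7	ATG	TAA	.
trnP	-	8280	8345	66	15	.	.	TGG
trnT	+	8361	8424	64	26	.	.	TGT
nad6	+	8451	8954	504	-1	ATT	TAA	.
cytb	+	8954	10088	1135	0	ATG	T(AA)	.
trnS2	+	10089	10156	68	26	.	.	TGA
nad1	-	10183	11121	939	27	ATA	TAA	.
trnL1	-	11149	11214	66	-40	.	.	TAG
16S	-	11175	12482	1308	22	.	.	.
trnV	-	12505	12569	65	-1	.	.	TAC
12S	-	12569	13369	801	242	.	.	.
CR	+	13612	13811	200	.	.	.	.
trnI	+	14318	14384	67	28	.	.	GAT
trnQ	-	14413	14480	68	3	.	.	TTG
trnM	+	14484	14549	66	-15	.	.	CAT
nad2	+	14535	15542	1008	-2	ATT	TAG	.
trnW	+	15541	15608	68	-1	.	.	TCA
trnC	-	15608	15670	63	0	.	.	GCA
trnY	-	15671	15735	65	0	.	.	GTA
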