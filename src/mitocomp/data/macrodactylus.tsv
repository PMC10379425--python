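# Palaemon macrodactylus complete mitogenome annotation (GenBank OQ512152),
# transcribed from the published annotation table of the deposited record.
# genome_length=15744  organism=Palaemon macrodactylus  accession=OQ512152
# Coordinates 1-based inclusive; intergenic = signed gap to the next feature
# ("." on the CR row, the published table's convention); negative = overlap.
symbol	strand	start	end	size	intergenic	start_codon	stop_codon	anticodon
cox1	+	1	1535	1535	0	ATG	CTA	.
trnL2	+	1536	1600	65	2	.	.	TAA
cox2	+	1603	2290	688	3	ATG	ACT	.
trnK	+	2294	2359	66	2	.	.	TTT
trnD	+	2362	2426	65	0	.	.	GTC
atp8	+	2427	2585	159	-7	ATT	TAA	.
atp6	+	2579	3253	675	-1	ATG	TAA	.
cox3	+	3253	4041	789	3	ATG	TAA	.
trnG	+	4045	4108	64	0	.	.	TCC
nad3	+	4109	4462	354	3	ATT	TAA	.
trnA	+	4466	4528	63	-1	.	.	TGC
trnR	+	4528	4595	68	3	.	.	TCG
trnN	+	4599	4662	64	-1	.	.	GTT
trnS1	+	4662	4728	67	0	.	.	TCT
trnE	+	4729	4796	68	-2	.	.	TTC
trnF	-	4795	4858	64	0	.	.	GAA
nad5	-	4859	6571	1713	12	ATT	TAA	.
trnH	-	6584	6645	62	0	.	.	GTG
nad4	-	6646	7962	1317	11	ATA	TAA	.
nad4l	-	7974	8273	300	7	ATG	TAA	.
trnP	-	8281	8346	66	15	.	.	TGG
trnT	+	8362	8425	64	26	.	.	TGT
nad6	+	8452	8955	504	-1	ATT	TAA	.
cytb	+	8955	10089	1135	0	ATG	ATT	.
trnS2	+	10090	10157	68	29	.	.	TGA
nad1	-	10187	11125	939	27	ATA	TAA	.
trnL1	-	11153	11218	66	-40	.	.	TAG
16S	-	11179	12515	1337	-6	.	.	.
trnV	-	12510	12574	65	-1	.	.	TAC
12S	-	12574	13376	803	331	.	.	.
CR	+	13708	13887	180	.	.	.	.
trnI	+	14327	14393	67	28	.	.	GAT
trnQ	-	14422	14489	68	3	.	.	TTG
trnM	+	14493	14558	66	0	.	.	CAT
nad2	+	14559	15551	993	-2	ATT	TAG	.
trnW	+	15550	15617	68	-1	.	.	TCA
trnC	-	15617	15679	63	0	.	.	GCA
trnY	-	15680	15744	65	0	.	.	GTA
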