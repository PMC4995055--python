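#genome_length=15220	topology=circular
Gene	Start	End	Size	Direction	IGN	Codons	AT_percent
cox1	1	1539	1539	Forward	2	ATG, TAA	65.0
trnL1	1542	1605	64	Forward	0	TAA	68.8
cox2	1606	2269	664	Forward	0	ATT, T--	69.0
trnK	2270	2339	70	Forward	6	CTT	72.8
trnD	2346	2407	62	Forward	9	GTC	64.5
atp8	2417	2563	147	Forward	-1	ATA, TAA	63.3
atp6	2563	3207	645	Forward	18	ATA, TAG	68.6
trnE	3226	3292	67	Forward	7	TTC	70.1
trnF	3300	3362	63	Reverse	-20	GAA	77.8
nad5	3348	5022	1675	Reverse	0	ATA, T--	73.0
trnH	5023	5083	61	Reverse	1	GTG	80.3
nad4	5085	6365	1281	Reverse	-4	ATG, TAG	69.1
nad4l	6362	6658	297	Reverse	2	ATG, TAA	75.8
trnT	6661	6722	62	Forward	0	TGT	77.4
trnP	6723	6783	61	Reverse	25	TGG	73.7
nad6	6809	7249	441	Forward	-1	ATA, TAA	72.6
cytb	7249	8382	1134	Forward	0	ATG, TAA	66.2
trnS2	8383	8439	57	Forward	-7	GCT	75.5
nad1	8433	9353	921	Reverse	0	ATA, TAA	72.5
trnL2	9360	9422	63	Reverse	0	TAG	82.5
rrnL	9423	10700	1278	Reverse	5		77.7
rrnS	10706	11476	771	Reverse	9		77.1
trnN	11486	11551	66	Forward	4	GTT	75.7
trnQ	11556	11626	71	Reverse	-7	TTG	88.8
trnV	11620	11683	64	Reverse	-3	TAC	73.4
trnR	11681	11745	65	Reverse	1	TCG	69.2
trnA	11747	11808	62	Reverse	0	TGC	75.8
nad3	11809	12161	353	Forward	1	ATT, T--	71.7
trnG	12163	12225	63	Forward	0	TCC	84.1
cox3	12226	13011	786	Forward	0	ATG, TAA	67.3
CR	13012	13933	920				65.9
trnI	13932	13997	66	Forward	-4	GAT	69.7
trnM	13994	14061	68	Forward	0	CAT	76.5
nad2	14062	15036	975	Forward	-2	ATA, TAA	68.5
trnW	15035	15097	63	Forward	-2	TCA	80.9
trnY	15096	15157	62	Reverse	0	GCA	80.7
trnC	15158	15220	63	Reverse	1	GTA	92.1
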