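# Detoxification / pesticide-resistance Pfam-domain repertoires of 12 Coleoptera
# species: number of proteins containing each domain (a protein counts once per
# domain). Guilds: scolytine = conifer- or coffee-feeding bark beetle
# (Scolytinae); plant_feeder = other angiosperm-feeding herbivores;
# other = non-herbivores. Total is the printed repertoire total per species.
species	guild	Lig_chan	p450	GST_N	GST_C	ABC_tran	UDPGT	COesterase	Inhibitor_I29	Total
Ityp	scolytine	33	84	31	27	75	27	59	23	359
Dpon	scolytine	17	93	24	22	74	23	63	22	338
Hham	scolytine	31	64	16	11	72	26	49	17	286
Agla	plant_feeder	56	120	24	18	77	62	105	19	481
Tcas	plant_feeder	45	133	35	32	89	29	56	16	435
Ldec	plant_feeder	40	114	29	22	129	50	118	37	539
Apla	plant_feeder	45	109	20	20	106	57	80	6	443
Cmac	plant_feeder	40	132	16	11	140	46	106	37	528
Dvir	plant_feeder	55	238	36	33	166	67	168	76	839
Otau	other	56	182	43	29	115	48	88	8	569
Atum	other	35	124	44	32	83	60	59	24	461
Nves	other	54	156	24	21	82	47	62	7	453
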