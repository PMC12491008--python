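food_id	name	species	share_pct	fat_pct	listed_content
cru-01	Northern shrimp	Pandalus borealis	32.0	4.1	0.01
cru-02	Hokkai shrimp	Aristaeomorpha foliacea	15.7	6.1	0.01
cru-03	Crab	Scylla serrata	17.2	3.6	0.01
cru-04	Japanese glass shrimp	Pasiphaea japonica	35.9	1.5	0.01
cru-05	Sergestid shrimp	Sergia lucens	29.7	1.3	<0.01
cru-06	Japanese king prawn	Marsupenaeus japonicus	38.9	0.8	<0.01
cru-07	Phoenix tail prawn	Penaeus vannamei	21.9	0.8	<0.01
cru-08	Pacific white shrimp	Litopenaeus vannamei	18.4	0.9	<0.01
cru-09	Ghost prawn	Palaemonetes paludosus	22.1	0.7	<0.01
cru-10	Mantis shrimp	Gonodactylus smithii	29.4	0.5	<0.01
cru-11	Whiskered velvet shrimp	Metapenaeopsis barbata	36.3	0.4	<0.01
cru-12	Blue shrimp	Litopenaeus stylirostris	23.5	0.6	<0.01
cru-13	Sagami lobster	Metanephrops sagamiensis	43.1	0.3	<0.01
cru-14	Big head prawn	Solenocera crassicornis	30.0	0.3	<0.01
cru-15	Armored lobster	Heterocarpus sibogae	27.8	0.3	<0.01
cru-16	Hard spear prawn	Parapenaeopsis hardwickii	32.2	0.2	<0.01
cru-17	Big head prawn	Solenocera alticarinata	26.3	0.2	<0.01
cru-18	Kuruma shrimp	Penaeus chinensis	25.8	0.2	<0.01
cru-19	Japanese spiny lobster	Panulirus japonicus	46.7	0.1	<0.01
cru-20	Crimson crab	Ranina ranina	43.7	0.1	<0.01
cru-21	Giant river shrimp	Macrobrachium rosenbergii	18.0	0.1	<0.01
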