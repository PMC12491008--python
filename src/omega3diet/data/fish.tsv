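food_id	name	species	share_pct	fat_pct	listed_content
fish-01	Mackerel	Scomber scombrus	20.5	39.4	0.08
fish-02	Pacific saury	Cololabis saira	21.0	21.8	0.05
fish-03	Starry butterfish	Stromateus stellatus	18.8	16.3	0.03
fish-04	Atlantic salmon	Salmo salar	16.7	14.9	0.02
fish-05	Shishamo	Spirinchus lanceolatus	47.6	4.9	0.02
fish-06	Antarctic toothfish	Dissostichus eleginoides	8.9	25.5	0.02
fish-07	Freshwater eel	Anguilla japonica	11.3	19.6	0.02
fish-08	Croaker	Larimichthys polyactis	22.8	8.0	0.02
fish-09	Runner	Rachycentron canadum	15.1	7.2	0.02
fish-10	Silverfish	Trichiurus japonicus	18.3	2.0	0.02
fish-11	Spotted tangingi	Scomberomorus guttatus	15.1	10.4	0.02
fish-12	Skipjack	Katsuwonus pelamis	27.7	5.6	0.02
fish-13	Flounder	Pseudorhombus arsius	9.5	16.1	0.02
fish-14	Croceine croaker	Larimichthys crocea	17.7	7.8	0.01
fish-15	Yellow croaker	Larimichthys croceus	15.7	1.6	0.01
fish-16	East Asian fourfinger threadfin	Eleutheronema rhadinum	17.5	7.2	0.01
fish-17	Spaniard	Scomberomorus commerson	11.9	10.4	0.01
fish-18	Thornfish	Terapon jarbua	14.0	8.2	0.01
fish-19	Chicken grunt	Parapristipoma trilineatum	20.6	5.4	0.01
fish-20	Rainbow trout	Oncorhynchus mykiss	16.1	6.8	0.01
fish-21	Japanese butterfish	Psenopsis anomala	12.4	8.7	0.01
fish-22	Southern mackerel	Scomber australasicus	26.5	4.0	0.01
fish-23	Sliver stripe round herring	Spratelloides gracilis	75.5	1.3	0.01
fish-24	Black sea bream	Acanthopagrus schlegelii	10.5	9.0	0.01
fish-25	Blackspot barracuda	Sphyraena forsteri	13.2	7.1	0.01
fish-26	Largemouth black bass	Micropterus salmoides	19.0	4.6	0.01
fish-27	Striped bass	Morone saxatilis	13.9	6.2	0.01
fish-28	Razor trevally	Mene maculata	29.4	2.9	0.01
fish-29	Scat	Scatophagus argus	6.5	12.6	0.01
fish-30	Big head	Hypophthalmichthys nobilis	11.0	7.2	0.01
fish-31	Yellow fin seabream	Acanthopagrus latus	13.2	6.0	0.01
fish-32	Purplish amberjack	Seriola dumerili	32.3	2.4	0.01
fish-33	Tiger grouper	Epinephelus fuscoguttatus	20.7	3.7	0.01
fish-34	Yellowfin sea bream	Acanthopagrus latus	15.1	4.8	0.01
fish-35	Rabbitfish	Siganus fuscescens	8.2	8.8	0.01
fish-36	Round scad	Decapterus macrosoma	28.1	2.4	0.01
fish-37	Golden thread	Nemipterus virgatus	18.9	3.3	0.01
fish-38	Japanese jack	Trachurus japonicus	30.9	2.0	0.01
fish-39	Spottedtail morwong	Cheilodactylus zonatus	18.2	3.4	0.01
fish-40	Silver sea bream	Rhabdosargus sarba	13.2	4.4	0.01
fish-41	Silver pomfret	Pampus argenteus	9.9	5.8	0.01
fish-42	Sand snapper	Lethrinus nebulosus	16.9	3.4	0.01
fish-43	Lizardfish	Saurida undosquamis	33.1	1.6	0.01
fish-44	Torpedo scad	Megalaspis cordyla	32.1	1.6	0.01
fish-45	Tang's snapper	Lipocheilus carnolabrum	13.9	3.7	0.01
fish-46	Redtail scad	Decapterus kurroides	29.6	1.7	0.01
fish-47	Ornate surgeonfish	Acanthurus dussumieri	8.1	6.2	0.01
fish-48	Sea mullet	Mugil cephalas	5.7	8.8	0.01
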