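food_id	name	species	share_pct	fat_pct	listed_content
mol-01	Argentine shortfin squid	Illex argentinus	52.2	2.0	0.01
mol-02	Green mussel	Perna viridis	46.4	2.2	0.01
mol-03	Giant Pacific oyster	Crassostrea gigas	37.9	1.6	0.01
mol-04	Yesso scallop	Patinopecten yessoensis	42.4	1.2	0.01
mol-05	Diphos sanguine	Sanguinolaria diphos	26.7	1.6	<0.01
mol-06	Bigfin reef squid	Sepioteuthis lessoniana	42.2	0.8	<0.01
mol-07	Corbicula clam	Corbicula fluminea	18.4	1.4	<0.01
mol-08	Undulating Venus	Paphia undulata	25.7	1.0	<0.01
mol-09	Chinese Venus	Cyclina sinensis	24.5	1.0	<0.01
mol-10	Inshore squid	Loligo edulis	41.3	0.4	<0.01
mol-11	Scallop	Patinopecten yessoensis	37.5	0.4	<0.01
mol-12	Cuttlefish	Sepia esculenta	46.4	0.3	<0.01
mol-13	Filipino Venus	Ruditapes philippinarum	24.6	0.5	<0.01
mol-14	Abalone	Haliotis diversicolor	66.7	0.1	<0.01
mol-15	Jackknife clam	Solen strictus	15.7	0.3	<0.01
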