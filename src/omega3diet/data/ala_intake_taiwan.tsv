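sex	age_low	age_high	category	mean	p50	p95	mean_flag	p50_flag	p95_flag
male	0	3	edible_oil	0.202	0.041	0.563	0	0	0
male	0	3	nut_seed	0.899	0.132	5.352	0	0	0
male	0	3	all	1.102	0.174	5.914	1	0	1
female	0	3	edible_oil	0.203	0.042	0.565	0	0	0
female	0	3	nut_seed	0.854	0.126	5.082	0	0	0
female	0	3	all	1.057	0.167	5.647	1	0	1
male	3	6	edible_oil	0.473	0.097	1.315	0	0	0
male	3	6	nut_seed	1.738	0.256	10.339	0	0	0
male	3	6	all	2.210	0.353	11.654	1	0	1
female	3	6	edible_oil	0.421	0.086	1.172	0	0	0
female	3	6	nut_seed	1.722	0.254	10.245	0	0	0
female	3	6	all	2.143	0.340	11.417	1	0	1
male	6	12	edible_oil	0.722	0.148	2.006	0	0	0
male	6	12	nut_seed	2.125	0.313	12.647	0	0	0
male	6	12	all	2.847	0.461	14.654	1	0	1
female	6	12	edible_oil	0.594	0.122	1.653	0	0	0
female	6	12	nut_seed	1.894	0.279	11.270	0	0	0
female	6	12	all	2.488	0.400	12.923	1	0	1
male	12	16	edible_oil	0.951	0.194	2.644	0	0	0
male	12	16	nut_seed	2.176	0.321	12.949	0	0	0
male	12	16	all	3.127	0.515	15.592	1	0	1
female	12	16	edible_oil	0.728	0.149	2.025	0	0	0
female	12	16	nut_seed	2.176	0.321	12.949	0	0	0
female	12	16	all	2.904	0.469	14.974	1	0	1
male	16	18	edible_oil	1.004	0.205	2.792	0	0	0
male	16	18	nut_seed	2.965	0.437	17.641	0	0	0
male	16	18	all	3.969	0.642	20.433	1	0	1
female	16	18	edible_oil	0.711	0.145	1.978	0	0	0
female	16	18	nut_seed	1.847	0.272	10.988	0	0	0
female	16	18	all	2.558	0.417	12.966	1	0	1
male	19	65	edible_oil	0.856	0.175	2.381	0	0	0
male	19	65	nut_seed	3.342	0.492	19.888	0	0	0
male	19	65	all	4.199	0.667	22.269	1	0	1
female	19	65	edible_oil	0.711	0.145	1.978	0	0	0
female	19	65	nut_seed	2.738	0.403	16.293	0	0	0
female	19	65	all	3.449	0.549	18.270	1	0	1
male	65	120	edible_oil	0.672	0.137	1.869	0	0	0
male	65	120	nut_seed	2.602	0.383	15.481	0	0	0
male	65	120	all	3.274	0.521	17.349	1	0	1
female	65	120	edible_oil	0.551	0.113	1.533	0	0	0
female	65	120	nut_seed	2.307	0.340	13.726	0	0	0
female	65	120	all	2.858	0.453	15.260	1	0	1
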