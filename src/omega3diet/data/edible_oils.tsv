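food_id	name	species	share_pct	fat_pct	listed_content
oil-01	Flaxseed oil		57.7	92.8	0.54
oil-02	Walnut oil		13.6	99.9	0.14
oil-03	Rapeseed oil		10.1	99.90	0.10
oil-04	Canola oil		7.66	99.9	0.08
oil-05	Soybean oil		6.82	100.0	0.07
oil-06	Corn oil		2.72	99.8	0.03
oil-07	Rice bran oil		1.86	99.9	0.02
oil-08	White sesame oil		1.68	100.0	0.02
oil-09	Chicken oil		1.48	99.8	0.01
oil-10	Lard		1.04	99.7	0.01
oil-11	Palm kernel oil		0.97	99.9	0.01
oil-12	Butter		1.06	82.7	0.01
oil-13	Sesame oil: black		0.78	99.7	0.01
oil-14	Olive oil		0.66	100.0	0.01
oil-15	Camellia oil		0.61	99.9	0.01
oil-16	Safflower oil		0.52	100.0	0.01
oil-17	Safflower oil (high oleic oil)		0.51	99.6	0.01
oil-18	Sunflower seed oil		0.51	100.0	0.01
oil-19	Grapeseed oil		0.34	100.00	<0.01
oil-20	Tallow		0.31	99.10	<0.01
oil-21	Pumpkin seed oil		0.30	99.90	<0.01
oil-22	Sunflower seed oil (high oleic acid)		0.12	99.90	<0.01
oil-23	Peanut oil		0.09	99.90	<0.01
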