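food_id	name	species	share_pct	fat_pct	listed_content
nut-01	Flaxseed		54.0	40.3	0.22
nut-02	Chia seed		63.0	31.8	0.20
nut-03	Awkeotsang	Ficus pumila	62.8	12.5	0.08
nut-04	Walnut		10.5	67.9	0.07
nut-05	Pistachio		0.4	52.7	<0.01
nut-06	White sesame		0.3	58.7	<0.01
nut-07	Black sesame		0.3	54.4	<0.01
nut-08	Macadamia nut		0.2	71.6	<0.01
nut-09	Pumpkin seed		0.3	47.9	<0.01
nut-10	Sunflower seed		0.2	51.9	<0.01
nut-11	Hazelnut		0.1	66.5	<0.01
nut-12	Cashew nut		0.2	43.7	<0.01
nut-13	Watermelon seed		0.2	37.7	<0.01
nut-14	Lotus nut		11.4	0.5	<0.01
nut-15	Peanut		0.1	43.9	<0.01
nut-16	Chestnut		6.2	0.8	<0.01
nut-17	Gingko nut		2.3	1.2	<0.01
nut-18	Almond		<0.05	49.8	<0.01
nut-19	Pine nut		0.2	69	<0.01
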