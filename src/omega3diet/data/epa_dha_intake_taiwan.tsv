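sex	age_low	age_high	category	mean	p50	p95	mean_flag	p50_flag	p95_flag
male	0	3	fish	0.152	0.129	0.258	0	0	1
male	0	3	crustacean	0.025	0.021	0.042	0	0	0
male	0	3	mollusk	0.002	0.002	0.004	0	0	0
male	0	3	all	0.180	0.152	0.304	0	0	1
female	0	3	fish	0.100	0.085	0.170	0	0	0
female	0	3	crustacean	0.017	0.014	0.028	0	0	0
female	0	3	mollusk	0.005	0.004	0.007	0	0	0
female	0	3	all	0.121	0.103	0.205	0	0	0
male	3	6	fish	0.146	0.124	0.248	0	0	0
male	3	6	crustacean	0.035	0.029	0.058	0	0	0
male	3	6	mollusk	0.011	0.009	0.018	0	0	0
male	3	6	all	0.192	0.162	0.325	0	0	1
female	3	6	fish	0.154	0.130	0.261	0	0	1
female	3	6	crustacean	0.027	0.022	0.045	0	0	0
female	3	6	mollusk	0.004	0.003	0.006	0	0	0
female	3	6	all	0.184	0.156	0.312	0	0	1
male	6	12	fish	0.157	0.134	0.267	0	0	1
male	6	12	crustacean	0.035	0.029	0.059	0	0	0
male	6	12	mollusk	0.027	0.021	0.042	0	0	0
male	6	12	all	0.219	0.184	0.369	0	0	1
female	6	12	fish	0.169	0.144	0.287	0	0	1
female	6	12	crustacean	0.036	0.030	0.060	0	0	0
female	6	12	mollusk	0.009	0.007	0.014	0	0	0
female	6	12	all	0.214	0.181	0.362	0	0	1
male	12	16	fish	0.165	0.141	0.281	0	0	1
male	12	16	crustacean	0.024	0.020	0.040	0	0	0
male	12	16	mollusk	0.006	0.005	0.009	0	0	0
male	12	16	all	0.195	0.165	0.330	0	0	1
female	12	16	fish	0.160	0.136	0.273	0	0	1
female	12	16	crustacean	0.030	0.025	0.050	0	0	0
female	12	16	mollusk	0.008	0.006	0.012	0	0	0
female	12	16	all	0.198	0.167	0.335	0	0	1
male	16	18	fish	0.175	0.149	0.298	0	0	1
male	16	18	crustacean	0.032	0.027	0.054	0	0	0
male	16	18	mollusk	0.006	0.005	0.010	0	0	0
male	16	18	all	0.214	0.181	0.362	0	0	1
female	16	18	fish	0.076	0.064	0.129	0	0	0
female	16	18	crustacean	0.027	0.023	0.046	0	0	0
female	16	18	mollusk	0.012	0.009	0.018	0	0	0
female	16	18	all	0.114	0.096	0.192	0	0	0
male	19	65	fish	0.332	0.282	0.565	1	1	1
male	19	65	crustacean	0.038	0.032	0.064	0	0	0
male	19	65	mollusk	0.016	0.012	0.025	0	0	0
male	19	65	all	0.386	0.327	0.654	1	1	1
female	19	65	fish	0.271	0.230	0.461	1	0	1
female	19	65	crustacean	0.031	0.026	0.051	0	0	0
female	19	65	mollusk	0.013	0.010	0.020	0	0	0
female	19	65	all	0.315	0.266	0.533	1	1	1
male	65	120	fish	0.558	0.474	0.949	1	1	1
male	65	120	crustacean	0.020	0.017	0.034	0	0	0
male	65	120	mollusk	0.013	0.010	0.021	0	0	0
male	65	120	all	0.592	0.502	1.004	1	1	1
female	65	120	fish	0.360	0.306	0.612	1	1	1
female	65	120	crustacean	0.015	0.012	0.025	0	0	0
female	65	120	mollusk	0.010	0.008	0.015	0	0	0
female	65	120	all	0.385	0.326	0.652	1	1	1
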