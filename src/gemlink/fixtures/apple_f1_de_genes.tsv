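trait_section	seq_id	delta_expression	q_value	chromosome	position_mb
PM	APPLE0FR00030459	-1.47	0.028	2	22.4
PM	APPLE0F000059353	1.67	0.026	5	15.5
PM	APPLE0FR00047019	-2.82	0.013	10	27.2
PM	APPLE0F000058978	-1.47	0.013	11	25.6
PM	APPLE0F000025011	1.71	2e-05	11	29.2
PM	APPLE0FR00035938	1.55	0.066	13	7.1
PM	APPLE0F000055730	-1.40	0.023	13	15.9
PM	APPLE0FR00044992	-1.28	0.046	12	18.9
PM	APPLE0F000015813	-1.47	0.013	12	19.1
PM	APPLE0F000001444	-1.47	0.008	12	23.2
PM	APPLE0FR00037713	-1.76	0.017	12	23.5
PM	APPLE0F000016461	1.25	0.013	12	26.6
PM	APPLE0F000004849	-1.79	0.023	12	27.1
PM	APPLE0F000054055	-1.52	0.015	12	28.1
PM	APPLE0F000013256	-4.76	0.066	12	28.3
PM	APPLE0F000001606	3.30	2e-12	12	28.7
PM	APPLE0FR00048809	3.59	8e-12	12	28.7
PM	APPLE0F000002331	-1.51	0.013	12	29.7
PM	APPLE0F000052120	-1.73	1e-05	12	30.1
PM	APPLE0F000021822	5.11	2e-09	12	30.1
PM	APPLE0F000001330	-1.79	0.004	12	30.1
PM	APPLE0F000026140	-1.59	0.008	12	30.2
PM	APPLE0F000027353	-1.64	0.004	12	30.7
PM	APPLE0F000002620	1.77	2e-04	12	30.9
PM	APPLE0F000004618	1.64	0.001	12	31.0
PM	APPLE0F000004776	1.39	0.002	12	31.1
PM	APPLE0F000002243	-1.40	0.013	12	31.1
PM	APPLE0F000017753	-1.47	0.023	12	31.2
PM	APPLE0F000016759	2.64	1e-06	12	31.2
PM	APPLE0F000012301	-1.58	0.004	12	31.5
WAA	APPLE0FR00041901	-0.87	0.011	15	9.5
WAA	APPLE0FR00031359	0.96	3e-04	15	9.5
WAA	APPLE0FR00067578	0.60	0.001	17	0.6
WAA	APPLE0FR00068101	-0.94	7e-04	17	1.4
WAA	APPLE00R00024612	-0.50	0.037	17	1.4
WAA	APPLE0F000027287	0.65	0.007	17	7.2
WAA	APPLE00R00016498	-0.46	0.008	17	9.8
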