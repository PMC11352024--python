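vein_id	length_mm	outer_diameter_mm	inner_diameter_mm
V_E_1	0.89	0.076	0.015
V_E_2	1.2	0.060	0.012
V_E_3	4.5	0.055	0.011
V_E_4	0.77	0.043	0.0086
V_E_5	0.74	0.026	0.0052
V_E_6	2.7	0.015	0.0029
V_E_7	4.9	0.019	0.0038
V_B_1	0.58	0.16	0.032
V_B_2	0.25	0.14	0.028
V_B_3	0.55	0.035	0.0070
V_B_4	0.83	0.042	0.0083
V_B_5	0.16	0.040	0.0079
V_B_6	1.6	0.035	0.0070
V_B_7	0.72	0.052	0.010
V_C_1	0.26	0.11	0.023
V_C_2	1.2	0.079	0.016
V_C_3	5.0	0.037	0.0074
V_C_4_E	2.4	0.030	0.0061
V_C_4_B	2.3	0.048	0.0095
V_C_5_E	2.3	0.023	0.0046
V_C_5_B	2.3	0.030	0.0060
V_C_6_E	0.44	0.021	0.0042
V_C_6_B	3.5	0.030	0.0060
ECV	0.62	0.037	0.0074
PCV	0.93	0.035	0.0070
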