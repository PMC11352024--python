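channel_id	node_a	node_b
V_E_1	IN	E1
V_E_2	E1	E2
V_E_3	E2	E3
V_E_4	E3	E4
V_E_5	E4	E5
V_E_6	E5	E6
V_E_7	E6	OUT
V_B_1	IN	B1
V_B_2	B1	B2
V_B_3	B2	B3
V_B_4	B3	B4
V_B_5	B4	B5
V_B_6	B5	B6
V_B_7	B6	OUT
V_C_1	E1	B1
V_C_2	E2	B2
V_C_3	E3	B3
V_C_4_E	E4	A
V_C_4_B	A	B4
V_C_5_E	E5	X
V_C_5_B	X	B5
V_C_6_E	E6	Y
V_C_6_B	Y	B6
ECV	A	X
PCV	X	Y
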