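cluster_id	branded	unbranded
cl_0	17	25
cl_1	37	46
cl_2	19	25
cl_3	29	23
cl_4	29	22
cl_5	36	52
cl_6	29	31
cl_7	23	26
cl_8	29	50
cl_9	54	29
cl_10	20	25
cl_11	21	22
cl_12	26	37
cl_13	28	25
cl_14	19	23
cl_15	34	15
cl_16	19	30
cl_17	28	39
cl_18	14	24
cl_19	24	16
cl_20	29	7
cl_21	21	27
cl_22	12	24
cl_23	43	34
cl_24	10	18
cl_25	29	38
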