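duplex_id	partner	reference_id	avg_dh	avg_dh_sd	avg_ds	avg_ds_sd	avg_dg37	avg_dg37_sd	avg_tm	vh_dh	vh_dh_sd	vh_ds	vh_ds_sd	vh_dg37	vh_dg37_sd	vh_tm	ddg37	ddg37_sd	dtm	internally_consistent
A-U	U	A-U	78.2	1.3	213.2	3.8	12.04	0.11	60.5	75.8	2.7	204.1	8.1	11.86	0.17	60.7	0.00		0.0	no
7A-U	U	A-U	71.1	5.7	204.4	18.6	7.73	0.14	42.3	61.4	3.6	173.2	11.5	7.71	0.06	43.1	4.15	0.18	-17.6	yes
AL-U	U	A-U	83.3	2.3	224.5	6.6	13.66	0.32	66.0	72.4	5.5	192.2	16.4	12.81	0.44	66.4	-0.95	0.47	5.7	yes
7AL-U	U	A-U	74.6	2.8	209.8	8.5	9.47	0.26	49.7	80.8	7.6	229.5	23.8	9.66	0.28	49.5	2.20	0.33	-11.2	yes
A-C	C	A-C	78.4	3.9	224.3	12.4	8.87	0.14	46.5	89.7	12.7	260.4	40.7	9.00	0.21	45.8	0.00		0.0	yes
7A-C	C	A-C	74.0	5.6	216.1	17.9	6.99	0.16	38.9	82.7	14.1	244.4	45.6	6.93	0.38	38.5	2.07	0.43	-7.3	yes
AL-C	C	A-C	71.3	0.9	199.2	2.8	9.48	0.11	50.4	62.1	1.0	170.2	3.1	9.27	0.02	51.3	-0.27	0.21	5.5	yes
7AL-C	C	A-C	71.8	2.8	203.5	8.9	8.73	0.12	46.8	67.6	2.1	190.1	6.8	8.61	0.05	46.8	0.39	0.22	1.0	yes
A-A	A	A-A	70.7	5.8	202.6	18.6	7.84	0.16	42.9	68.4	10.2	195.4	32.5	7.80	0.33	42.8	0.00		0.0	yes
7A-A	A	A-A	72.3	4.1	205.9	12.7	8.49	0.19	45.6	79.1	7.1	227.9	22.6	8.53	0.14	45.0	-0.73	0.36	2.2	no
AL-A	A	A-A	64.2	3.8	180.5	11.7	8.23	0.18	45.4	58.5	4.1	162.5	13.0	8.13	0.10	45.7	-0.33	0.34	2.9	yes
7AL-A	A	A-A	73.2	2.0	204.6	5.9	9.80	0.17	51.5	67.6	2.1	187.0	6.7	9.60	0.07	51.8	-1.80	0.34	9.0	yes
A-G	G	A-G	64.9	2.2	197.0	6.8	8.73	0.13	47.1	64.5	3.3	180.3	10.3	8.61	0.08	47.3	0.00		0.0	yes
7A-G	G	A-G	59.4	1.5	166.8	4.0	7.62	0.06	42.8	60.0	4.3	168.8	13.9	7.62	0.08	42.8	0.99	0.11	-4.5	yes
AL-G	G	A-G	69.1	2.8	192.1	9.0	9.49	0.02	50.9	61.1	1.0	167.0	3.2	9.32	0.02	51.8	-0.71	0.08	4.5	yes
7AL-G	G	A-G	74.8	2.4	208.9	7.7	9.98	0.08	52.0	71.8	2.6	199.8	8.3	9.89	0.08	52.2	-1.28	0.11	4.90	yes
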