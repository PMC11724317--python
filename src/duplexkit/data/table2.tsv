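duplex_id	partner	reference_id	ddg37_exp	nmr_orientation	dg_pred	ddg_pred	md_orientation	mean_hbonds
A-U	U	A-U	0.00	anti-anti	1.86	0.00	anti-anti	1.98
7A-U	U	A-U	4.15		5.43	3.57	anti-anti	1.16
7AL-U	U	A-U	2.20		2.85	0.99	syn-anti	1.00
A-C	C	A-C	0.00		4.34	0.00	anti-syn	1.00
7A-C	C	A-C	2.07		5.51	1.17	syn-anti	0.97
7AL-C	C	A-C	0.39		4.76	0.42	anti-anti	0.99
A-A	A	A-A	0.00	anti-anti	3.48	0.00	anti-anti	0.96
7A-A	A	A-A	-0.73	anti-anti	1.50	-1.98	anti-anti	1.99
7AL-A	A	A-A	-1.80	anti-anti	1.44	-2.04	anti-anti	1.99
A-G	G	A-G	0.00		2.81	0.00	syn-anti	1.99
7A-G	G	A-G	0.99	syn-anti	2.10	-0.71	syn-anti	1.54
7AL-G	G	A-G	-1.28	syn-anti	1.22	-1.59	syn-anti	1.75
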