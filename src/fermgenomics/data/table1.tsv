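ferm_id	nacl_mM	aa_factor	temperature_C	pH	aeration	od_max	mu_max	day	replicate_group	transcriptome
F1	0	2.0	37	5.2	N2	7.21	0.80	1		1
F2	300	2.0	37	5.2	N2	6.90	0.78	1		1
F3	0	1.1	37	5.2	O2	7.05	0.71	1		1
F4	300	1.1	37	5.2	O2	6.98	0.70	1		1
F5	0	2.0	28	5.2	O2	7.73	0.55	1		1
F6	300	2.0	28	5.8	O2	6.03	0.55	1	a	1
F7	300	2.0	28	5.2	O2	7.35	0.44	2		1
F8	0	1.1	28	5.2	N2	6.96	0.45	2	b	1
F9	300	1.1	28	5.2	N2	6.23	0.54	2		1
F10	0	2.0	37	6.4	O2	6.60	0.57	2		1
F11	300	2.0	37	6.4	O2	5.30	0.44	2		1
F12	0	1.1	28	5.8	N2	6.60	0.48	2	c	1
F13	0	1.1	37	6.4	N2	6.56	0.58	3		1
F14	300	1.1	37	6.4	N2	6.07	0.53	3		1
F15	0	2.0	28	6.4	N2	5.85	0.31	3		1
F16	300	2.0	28	6.4	N2	4.16	0.23	3		1
F17	0	1.1	28	6.4	O2	7.74	0.32	3		1
F18	0	2.0	37	5.8	N2	6.94	0.71	3	d	1
F19	300	1.1	28	6.4	O2	4.93	0.47	4		1
F20	0	2.0	37	5.8	N2	5.01	0.76	4	d	1
F21	300	2.0	37	5.8	N2	4.68	0.75	4		1
F22	0	1.1	37	5.8	O2	5.92	0.65	4		1
F23	300	1.1	37	5.8	O2	6.07	0.60	4		1
F24	0	1.1	28	5.2	N2	6.91	0.65	4	b	1
F25	0	2.0	28	5.8	O2	6.14	0.29	5	e	1
F26	300	2.0	28	5.8	O2	4.74	0.28	5	a	1
F27	0	1.1	28	5.8	N2	6.23	0.24	5	c	1
F28	300	1.1	28	5.8	N2	4.84	0.23	5		1
F29	0	2.0	28	5.8	O2	6.22	0.38	5	e	1
F30	0	2.0	37	5.8	N2	5.94	0.71	5	d	0
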