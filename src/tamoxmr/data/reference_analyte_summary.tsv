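analyte	mean	sd	median	min	max	n_not_detected
tamoxifen	173.53	67.68	169.76	41.4	402.10	0
ndm_tam	235.53	97.04	220.53	33.20	810.16	0
z_endoxifen	5.55	3.26	4.90	0.55	18.23	0
z_4oh_tam	2.46	1.20	2.45	0.12	5.66	0
e_endoxifen	0.02	0.07	0.0	0.03	0.37	249
4p_oh_tam	3.13	1.32	2.93	0.37	8.72	0
4p_oh_ndm_tam	3.84	1.93	3.56	0.19	15.66	1
tam_n_oxide	13.47	7.43	11.62	1.41	58.03	0
e_4oh_tam_o_gluc	0.23	0.17	0.18	0.03	1.19	1
ez_4oh_ndm_tam_gluc	1.12	1.02	0.88	0.10	11.49	0
ez_tam_n_gluc	0.32	0.32	0.24	0.03	2.45	1
e_a_oh_tam	0.36	0.17	0.37	0.02	1.02	8
z_a_oh_tam	0.04	0.03	0.04	0.02	0.19	116
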