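snp_id	ea_beta	concordant	adj_r2_pct	adj_or	eaf	power_pct	post_0.1pct	post_1pct	post_5pct	post_10pct
rs79210963	-0.016	yes	0.021	0.931	0.89	22.9	75.0	96.8	99.3	99.7
rs7610856	0.013	no	0.022	0.955	0.41	22.8	74.9	96.8	99.3	99.7
rs10896636	0.012	no	0.020	0.956	0.67	17.8	68.7	95.6	99.1	99.5
rs756912	-0.015	yes	0.022	0.956	0.51	22.7	74.8	96.7	99.3	99.7
rs6449503	0.018	no	0.020	0.961	0.51	12.9	60.0	93.7	98.7	99.3
rs7336518	-0.016	yes	0.014	0.964	0.13	1.5	13.4	60.6	88.5	93.9
rs143283559	0.014	no	0.017	0.965	0.72	4.6	32.8	83.0	96.1	98.0
rs11210935	0.015	no	0.014	0.973	0.77	1.2	10.9	55.1	86.0	92.5
rs77000541	-0.014	yes	0.018	0.974	0.33	1.6	14.1	62.2	89.2	94.3
rs2819344	0.014	no	0.017	0.983	0.62	0.3	3.0	23.3	60.4	75.3
rs4500960	-0.013	no	0.017	1.017	0.47	0.3	3.0	23.3	60.4	75.3
rs28360516	-0.012	no	0.013	1.027	0.70	1.4	12.6	59.0	87.8	93.5
rs7522116	0.011	yes	0.015	1.029	0.56	3.0	23.8	75.8	94.0	96.9
rs7593947	0.014	yes	0.018	1.040	0.51	12.5	59.1	93.5	98.6	99.3
rs11694989	0.011	yes	0.021	1.044	0.43	17.9	68.8	95.7	99.1	99.5
rs320700	0.013	yes	0.024	1.054	0.65	36.4	85.3	98.3	99.7	99.8
rs3957165	0.015	yes	0.020	1.056	0.83	14.7	63.6	94.6	98.9	99.4
rs10791106	0.011	yes	0.026	1.056	0.54	46.9	89.9	98.9	99.8	99.9
rs2992632	0.016	yes	0.025	1.060	0.74	36.8	85.5	98.3	99.7	99.8
rs10773002	0.022	yes	0.043	1.087	0.28	91.0	99.0	99.9	100.0	100.0
rs4378243	0.019	yes	0.044	1.112	0.85	91.5	99.1	99.9	100.0	100.0
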