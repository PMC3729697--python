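# Published whole-mtDNA age estimates for haplogroups N1a1b/I (table I) and W (table W).
# Columns: molecular divergences (substitutions, hotspot-masked) and the ages (ky) they
# were converted to with the purifying-selection-corrected clock, for both the
# maximum-likelihood (ml) and the rho estimators, with 95% CI endpoints in ky.
# These rows are the calibration anchors for the anchor-calibrated ClockModel.
table	clade	n	ml	ml_se	ml_age	ml_lo	ml_hi	rho	sigma	rho_age	rho_lo	rho_hi
I	N1a1b	196	10.3	0.9	28.6	23.5	33.9	10.7	3.1	29.8	12.2	48.5
I	N1a1b1	4	7.7	1.1	21.1	14.9	27.5	8.5	3.0	23.3	6.9	41.1
I	N1a1b1a	3	7.1	0.9	19.3	14.6	24.2	7.0	3.2	19.0	1.8	37.8
I	N1a1b1a1	2	2.3	0.9	5.9	1.3	10.6	2.0	1.0	5.2	0.1	10.5
I	I	192	7.4	0.3	20.1	18.4	21.9	8.7	1.2	23.8	16.9	30.9
I	I1	70	6.1	0.3	16.3	14.6	18.0	8.7	3.2	23.9	6.6	42.7
I	I1a	45	4.4	0.3	11.6	9.9	13.3	7.0	4.4	18.9	-4.2	44.9
I	I1a1	41	1.9	0.1	4.9	4.2	5.6	2.2	0.3	5.9	4.3	7.4
I	I1a1a	19	1.5	0.1	3.8	3.3	4.4	1.7	0.1	4.4	3.6	5.1
I	I1a1b	4	0.5	0.2	1.4	0.5	2.2	0.5	0.1	1.3	0.7	1.9
I	I1a1c	4	1.0	0.2	2.5	1.3	3.7	1.3	0.7	3.2	-0.2	6.8
I	I1a1d	2	0.7	0.2	1.8	1.0	2.6	1.5	0.8	3.9	0.1	7.8
I	I1b	11	5.0	0.4	13.4	11.3	15.5	4.9	0.7	13.1	9.3	17.0
I	I1c	6	3.9	0.4	10.3	8.4	12.2	5.3	2.7	14.3	0.3	29.4
I	I1c1	5	2.7	0.3	7.2	5.4	9.0	3.6	1.7	9.5	0.8	18.7
I	I1c1a	4	1.5	0.3	4.0	2.5	5.4	1.8	0.4	4.6	2.3	6.8
I	I5	29	6.8	0.3	18.4	16.4	20.3	8.2	2.4	22.6	9.1	36.9
I	I5a	24	5.9	0.4	16.0	14.0	17.9	6.8	1.5	18.4	10.3	26.9
I	I5a1	9	3.5	0.4	9.2	7.1	11.3	3.6	0.7	9.4	5.5	13.4
I	I5a2	10	4.6	0.4	12.3	10.2	14.4	5.4	3.3	14.5	-2.9	33.6
I	I5a2a	8	0.6	0.1	1.6	1.0	2.1	0.6	0.1	1.6	1.2	2.0
I	I5a3	2	1.8	0.4	4.8	2.8	6.8	2.0	1.0	5.2	0.1	10.5
I	I5a4	3	2.1	0.4	5.6	3.5	7.8	2.7	1.1	7.0	1.3	12.9
I	I5b	2	3.3	0.5	8.8	6.3	11.2	3.5	1.8	9.2	0.2	18.8
I	I6	4	6.8	0.4	18.4	16.2	20.6	8.5	3.3	23.3	5.6	42.6
I	I6a	2	2.0	0.3	5.3	3.5	7.0	2.5	1.3	6.5	0.1	13.2
I	I6b	2	4.9	0.5	13.1	10.4	15.8	5.5	2.8	14.8	0.3	30.4
I	I7	2	3.5	0.5	9.1	6.3	11.9	3.0	1.5	7.9	0.2	16.0
I	node-152	65	5.8	1.2	15.5	8.8	22.5	5.5	1.7	14.9	5.8	24.4
I	I2'3	64	4.7	0.4	12.6	10.4	14.7	4.6	0.7	12.2	8.2	16.2
I	I2	46	2.6	0.2	6.8	6.0	7.6	3.4	0.2	9.1	8.0	10.2
I	I2a	10	1.8	0.2	4.7	3.8	5.7	2.3	0.4	6.0	3.9	8.2
I	I2a1	4	1.3	0.2	3.2	2.1	4.4	2.0	0.8	5.2	1.4	9.2
I	I2b	4	0.7	0.2	1.7	0.5	2.9	0.8	0.2	1.9	1.0	2.9
I	I2c	6	1.8	0.2	4.7	3.6	5.8	1.5	0.3	3.9	2.3	5.5
I	I2d	3	1.1	0.4	3.0	1.1	4.8	1.0	0.3	2.6	0.9	4.3
I	I2e	2	1.2	0.3	3.1	1.4	4.8	1.0	0.5	2.6	0.1	5.2
I	I3	18	4.0	0.3	10.6	8.8	12.4	3.9	0.6	10.3	7.3	13.4
I	I3a	10	2.8	0.2	7.4	6.1	8.7	2.6	0.3	6.8	5.2	8.4
I	I3a1	2	2.3	0.3	6.1	4.7	7.5	3.5	1.8	9.2	0.2	18.8
I	I3b	2	1.0	0.3	2.6	1.1	4.2	1.0	0.5	2.6	0.1	5.2
I	I3c	3	3.5	0.3	9.4	7.6	11.2	6.0	2.9	16.2	0.9	32.7
I	I4	19	5.6	0.5	15.1	12.3	18.0	3.7	1.1	9.9	4.3	15.7
I	I4a	17	2.4	0.2	6.4	5.4	7.4	2.4	0.3	6.3	5.0	7.7
I	I4a1	6	2.2	0.2	5.7	4.7	6.7	3.2	0.6	8.3	5.3	11.5
I	I4b	2	3.2	0.5	8.4	5.8	10.9	3.5	1.8	9.2	0.2	18.8
W	W	223	6.2	0.5	16.8	14.2	19.5	6.8	0.8	18.4	14.1	22.8
W	W1	93	3.9	0.3	10.4	9.0	11.9	4.0	0.4	10.7	8.5	12.9
W	W1a	25	0.6	0.1	1.6	1.2	2.0	0.7	0.0	1.8	1.5	2.0
W	W1b	15	1.1	0.2	2.8	1.9	3.6	1.6	0.6	4.2	1.0	7.4
W	W1b1	11	0.8	0.1	2.0	1.3	2.6	1.0	0.1	2.6	2.0	3.2
W	W1e	5	1.6	0.4	4.2	2.4	6.1	2.4	1.4	6.3	-1.1	14.0
W	W1f	3	2.7	0.5	7.2	4.8	9.6	2.7	1.6	7.0	-1.0	15.4
W	node-119	27	3.3	0.2	8.6	7.4	9.8	4.1	0.6	11.0	7.6	14.5
W	W1c	16	3.0	0.2	7.9	6.8	9.0	4.4	0.7	11.8	7.9	15.8
W	W1c1	6	1.8	0.2	4.6	3.6	5.7	2.3	0.6	6.1	3.2	9.0
W	W1g	3	0.8	1.3	2.0	-4.6	8.9	0.7	0.4	1.7	-0.5	4.0
W	node-194	119	6.2	0.3	16.8	15.0	18.7	7.4	0.9	20.3	15.5	25.2
W	W3	45	5.5	0.3	14.8	13.0	16.6	5.8	1.2	15.5	8.9	22.5
W	W3a	33	4.4	0.3	11.8	10.1	13.6	4.8	1.0	12.7	7.4	18.2
W	W3a1	29	3.7	0.2	9.8	8.7	10.9	3.8	0.2	10.0	8.8	11.3
W	W3a1a	5	3.5	0.2	9.1	8.0	10.3	5.8	1.4	15.6	8.0	23.5
W	W3a1a1	2	3.2	0.2	8.3	7.1	9.5	7.0	3.5	19.0	0.4	39.5
W	W3a1a2	2	2.4	0.3	6.3	4.6	8.0	3.5	1.8	9.2	0.2	18.8
W	W3a1b	5	3.3	0.2	8.7	7.5	9.9	4.0	1.2	10.6	4.3	17.2
W	W3a1c	3	1.4	0.3	3.7	2.2	5.2	1.3	0.4	3.5	1.2	5.8
W	W3a2	3	2.1	1.7	5.6	-3.0	14.8	2.7	1.6	7.0	-1.0	15.4
W	W3b	11	3.8	0.3	10.0	8.2	11.8	3.7	0.7	9.9	6.4	13.4
W	W3b1	3	0.4	0.2	1.0	0.2	1.8	0.3	0.1	0.9	0.3	1.4
W	W4	14	4.6	0.4	12.2	9.9	14.7	4.6	0.8	12.2	7.7	16.8
W	W4a	8	3.7	0.4	9.8	7.6	12.0	3.8	0.9	9.9	5.1	14.8
W	W5	29	4.6	0.3	12.2	10.5	14.0	5.8	2.3	15.6	3.6	28.4
W	W5a	24	3.2	0.3	8.4	6.9	9.8	4.0	1.2	10.6	4.2	17.2
W	W5a1	18	2.7	0.2	7.1	5.9	8.4	3.4	1.0	9.1	3.7	14.7
W	W5a1a	16	2.1	0.2	5.5	4.5	6.6	2.4	0.3	6.4	4.9	7.8
W	W5a1a1	5	1.6	0.2	4.1	3.0	5.2	2.2	0.6	5.7	2.6	8.9
W	W5a1a1a	2	0.4	0.1	1.0	0.3	1.7	0.5	0.3	1.3	0.0	2.6
W	W5a2	5	2.0	0.3	5.1	3.7	6.5	2.0	0.5	5.2	2.7	7.7
W	W5b	4	3.5	0.4	9.3	7.3	11.4	4.3	1.9	11.3	1.2	22.0
W	W6	29	4.7	0.3	12.6	10.8	14.5	5.4	1.1	14.4	8.3	20.7
W	node-16192	26	4.2	0.3	11.2	9.8	12.6	4.3	0.4	11.6	9.5	13.6
W	W6a	5	1.9	0.4	5.0	3.1	6.8	1.6	0.6	4.2	1.3	7.1
W	W6b	6	3.1	0.3	8.1	6.4	9.7	4.3	1.1	11.5	5.6	17.6
W	W6c	2	3.6	0.4	9.6	7.7	11.4	5.0	2.5	13.4	0.3	27.5
W	W7	4	3.7	0.7	9.9	6.0	14.0	2.8	1.2	7.2	1.1	13.6
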