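sample_id	dosage_form	source_type	locus	n_listed	n_identified	pct_identified_printed	pct_not_identified_printed
S01	POWDER	IN_HOUSE	ITS2	25	17	68.00	32.00
S01	POWDER	IN_HOUSE	RBCL	25	14	56.00	44.00
S02	POWDER	IN_HOUSE	ITS2	27	12	44.44	55.56
S02	POWDER	IN_HOUSE	RBCL	27	19	70.37	29.63
S03	POWDER	IN_HOUSE	ITS2	30	16	53.33	46.67
S03	POWDER	IN_HOUSE	RBCL	30	23	76.67	23.33
S04	POWDER	IN_HOUSE	ITS2	28	16	57.14	42.86
S04	POWDER	IN_HOUSE	RBCL	28	22	78.57	21.43
S06	POWDER	IN_HOUSE	ITS2	12	6	50.00	50.00
S06	POWDER	IN_HOUSE	RBCL	12	8	66.67	33.33
S07	POWDER	IN_HOUSE	ITS2	14	7	50.00	50.00
S07	POWDER	IN_HOUSE	RBCL	14	9	64.29	35.71
S08	POWDER	IN_HOUSE	ITS2	11	8	72.73	27.27
S08	POWDER	IN_HOUSE	RBCL	11	8	72.73	27.27
S10	POWDER	IN_HOUSE	ITS2	7	6	85.71	14.29
S10	POWDER	IN_HOUSE	RBCL	7	6	85.71	14.29
S11	POWDER	IN_HOUSE	ITS2	10	7	70.00	30.00
S11	POWDER	IN_HOUSE	RBCL	10	8	80.00	20.00
S12	POWDER	IN_HOUSE	ITS2	5	5	100.00	0.00
S12	POWDER	IN_HOUSE	RBCL	5	4	80.00	20.00
S13	POWDER	IN_HOUSE	ITS2	4	4	100.00	0.00
S13	POWDER	IN_HOUSE	RBCL	4	3	75.00	25.00
S14	POWDER	IN_HOUSE	ITS2	8	6	75.00	25.00
S14	POWDER	IN_HOUSE	RBCL	8	7	87.50	12.50
S15	POWDER	IN_HOUSE	ITS2	19	11	57.89	42.11
S15	POWDER	IN_HOUSE	RBCL	19	12	63.16	36.84
S16	POWDER	IN_HOUSE	ITS2	10	8	80.00	20.00
S16	POWDER	IN_HOUSE	RBCL	10	9	90.00	10.00
S17	POWDER	IN_HOUSE	ITS2	15	8	53.33	46.67
S17	POWDER	IN_HOUSE	RBCL	15	12	80.00	20.00
S18	POWDER	IN_HOUSE	ITS2	15	7	46.67	53.33
S18	POWDER	IN_HOUSE	RBCL	15	7	46.67	53.33
S19	POWDER	IN_HOUSE	ITS2	9	2	22.22	77.78
S19	POWDER	IN_HOUSE	RBCL	9	5	55.56	44.44
S20	POWDER	IN_HOUSE	ITS2	5	4	80.00	20.00
S20	POWDER	IN_HOUSE	RBCL	5	3	60.00	40.00
S22	POWDER	IN_HOUSE	ITS2	12	7	58.33	41.67
S22	POWDER	IN_HOUSE	RBCL	12	9	75.00	25.00
S23	POWDER	IN_HOUSE	ITS2	6	6	100.00	0.00
S23	POWDER	IN_HOUSE	RBCL	6	5	83.33	16.67
S24	POWDER	IN_HOUSE	ITS2	6	5	83.33	16.67
S24	POWDER	IN_HOUSE	RBCL	6	5	83.33	16.67
S25	CAPSULE	REGISTERED	ITS2	6	5	83.33	16.67
S25	CAPSULE	REGISTERED	RBCL	6	5	83.33	16.67
S26	CAPSULE	REGISTERED	ITS2	5	5	100.00	0.00
S26	CAPSULE	REGISTERED	RBCL	5	5	100.00	0.00
S27	POWDER	REGISTERED	ITS2	4	4	100.00	0.00
S27	POWDER	REGISTERED	RBCL	4	4	100.00	0.00
S28	CAPSULE	REGISTERED	ITS2	4	2	50.00	50.00
S28	CAPSULE	REGISTERED	RBCL	4	2	50.00	50.00
S29	CAPSULE	REGISTERED	ITS2	17	8	47.06	52.94
S29	CAPSULE	REGISTERED	RBCL	17	9	52.94	47.06
S31	CAPSULE	REGISTERED	ITS2	4	3	75.00	25.00
S31	CAPSULE	REGISTERED	RBCL	4	3	75.00	25.00
S32	CAPSULE	REGISTERED	ITS2	1	1	100.00	0.00
S32	CAPSULE	REGISTERED	RBCL	1	1	100.00	0.00
S33	CAPSULE	REGISTERED	ITS2	1	1	100.00	0.00
S33	CAPSULE	REGISTERED	RBCL	1	1	100.00	0.00
S34	TABLET	REGISTERED	ITS2	4	0	0.00	100.00
S34	TABLET	REGISTERED	RBCL	4	2	50.00	50.00
S35	TABLET	REGISTERED	ITS2	6	6	100.00	0.00
S35	TABLET	REGISTERED	RBCL	6	6	100.00	0.00
S36	TABLET	REGISTERED	ITS2	6	6	100.00	0.00
S36	TABLET	REGISTERED	RBCL	6	6	100.00	0.00
S38	TABLET	REGISTERED	ITS2	1	1	100.00	0.00
S38	TABLET	REGISTERED	RBCL	1	1	100.00	0.00
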