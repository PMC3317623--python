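cluster	trait	kind	low	high
1	dorsal_gap	hard	present	
1	upper_jaw_sheath	hard	present	
1	oral_disc_margin	hard	continuous_with_snout	
1	ltrf	hard	6(3–6)/3(1)|6(3–6)/3|7(3–7)/3	
1	ODW/BW	soft	56	84
1	A1len/ODW	soft	82	90
1	A1num	soft	220	301
1	JW/ODW	soft	31	46
1	MCL/JW	soft	0.04	0.11
1	DG/BW	soft	67	85
1	SMP	soft	33	94
1	MP	soft	101	175
1	EH/BH	soft	69	85
1	SE/BL	soft	32	39
1	NH/BH	soft	57	82
1	NH/EH	soft	82	97
1	RN/NP	soft	60	92
1	TAL/BL	soft	155	183
2	dorsal_gap	hard	present	
2	oral_disc_margin	hard	shallow_crevice|free	
2	ltrf	hard	7(5–7)/3|8(5–8)/3|8(6–8)/3	
2	ODW/BW	soft	74	108
2	A1len/ODW	soft	21	59
2	A1num	soft	95	241
2	JW/ODW	soft	30	34
2	DG/BW	soft	14	59
2	MP	soft	148	377
2	SMP	soft	190	368
2	EH/BH	soft	71	84
2	SE/BL	soft	35	49
2	NH/BH	soft	64	92
2	NH/EH	soft	86	112
2	RN/NP	soft	107	194
2	TAL/BL	soft	146	184
3	dorsal_gap	hard	absent	
3	upper_jaw_sheath	hard	present	
3	oral_disc_margin	hard	free	
3	ltrf	hard	7(5–7)/3	
3	ODW/BW	soft	68	79
3	A1len/ODW	soft	45	52
3	A1num	soft	126	235
3	JW/ODW	soft	30	38
3	SMP	soft	222	318
3	MP	soft	206	522
3	EH/BH	soft	68	80
3	SE/BL	soft	35	49
3	NH/BH	soft	68	80
3	NH/EH	soft	89	101
3	RN/NP	soft	78	109
3	TAL/BL	soft	140	188
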