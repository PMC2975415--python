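id	position	label
hsH3.1	4	P
hsH3.1	9	P
hsH3.1	14	P
hsH3.1	18	P
hsH3.1	23	P
hsH3.1	27	P
hsH3.1	36	P
hsH3.1	37	P
hsH3.1	56	P
hsH3.1	64	N
hsH3.1	79	N
hsH3.1	115	N
hsH3.1	122	N
hsH4	5	P
hsH4	8	P
hsH4	12	P
hsH4	16	P
hsH4	20	N
hsH4	31	P
hsH4	44	P
hsH4	59	P
hsH4	77	P
hsH4	79	P
hsH4	91	P
hsH2A.1	5	P
hsH2A.1	9	P
hsH2A.1	13	N
hsH2A.1	15	N
hsH2A.1	36	N
hsH2A.1	74	N
hsH2A.1	75	N
hsH2A.1	95	N
hsH2A.1	99	N
hsH2A.1	118	N
hsH2A.1	119	N
hsH2A.1	125	N
hsH2A.1	127	N
hsH2A.1	129	N
hsH2B.1	5	P
hsH2B.1	11	N
hsH2B.1	12	P
hsH2B.1	15	P
hsH2B.1	16	P
hsH2B.1	20	P
hsH2B.1	23	P
hsH2B.1	24	N
hsH2B.1	27	N
hsH2B.1	28	N
hsH2B.1	30	N
hsH2B.1	34	N
hsH2B.1	40	N
hsH2B.1	43	N
hsH2B.1	46	N
hsH2B.1	57	N
hsH2B.1	85	N
hsH2B.1	105	N
hsH2B.1	108	N
hsH2B.1	113	N
hsH2B.1	116	N
hsH2B.1	117	N
hsH2B.1	120	N
hsH2B.1	122	N
hsH2B.1	125	N
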