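id	position	label
atH3.2	4	N
atH3.2	9	P
atH3.2	14	P
atH3.2	18	P
atH3.2	23	P
atH3.2	27	P
atH3.2	36	P
atH3.2	37	N
atH3.2	56	P
atH3.2	64	N
atH3.2	79	N
atH3.2	90	N
atH3.2	115	N
atH3.2	122	N
atH3.3	4	N
atH3.3	9	P
atH3.3	14	P
atH3.3	18	P
atH3.3	23	P
atH3.3	27	P
atH3.3	36	P
atH3.3	37	N
atH3.3	56	P
atH3.3	64	N
atH3.3	79	N
atH3.3	90	N
atH3.3	115	N
atH3.3	122	N
atH4	5	P
atH4	8	P
atH4	12	P
atH4	16	P
atH4	20	P
atH4	31	N
atH4	44	N
atH4	59	N
atH4	77	N
atH4	79	N
atH4	91	N
atH2B.6	3	P
atH2B.6	4	P
atH2B.6	8	P
atH2B.6	9	P
atH2B.6	14	P
atH2B.6	15	P
atH2B.7	3	P
atH2B.7	4	P
atH2B.7	8	P
atH2B.7	9	P
atH2B.7	14	P
atH2B.7	15	P
atH2B.10	3	P
atH2B.10	6	P
atH2B.10	11	P
atH2B.10	12	P
atH2B.10	25	P
atH2B.10	32	P
atH2B.10	35	P
atH2A.1	5	P
atH2A.4	144	P
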