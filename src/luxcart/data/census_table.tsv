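genus	organism	n_canonical	n_double	double_topologies	n_luxI_solo	n_luxR_solo
Novosphingobium	Novosphingobium lindaniclasticum LE124	1	0		0	0
Novosphingobium	Novosphingobium pentaromativorans PP1Y	2	0		0	1
Novosphingobium	Novosphingobium pentaromativorans US6-1	1	0		0	0
Novosphingobium	Novosphingobium resinovorum KF1	2	0		0	2
Novosphingobium	Novosphingobium sp. AP12	1	0		0	0
Novosphingobium	Novosphingobium sp. RR 2-17	1	0		0	0
Novosphingobium	Novosphingobium tardaugens NBRC 16725	0	0		0	2
Sphingobium	Sphingobium baderi LL03	0	2	T3;T5	1	3
Sphingobium	Sphingobium chinhatense IP26	1	0		1	0
Sphingobium	Sphingobium chlorophenolicum NBRC 16172	2	0		1	1
Sphingobium	Sphingobium chlorophenolicum L1	0	1	T1	1	1
Sphingobium	Sphingobium herbicidovorans NBRC 16415	1	1	T3	0	1
Sphingobium	Sphingobium indicum B90A	0	1	T1	1	1
Sphingobium	Sphingobium japonicum UT26S	2	1	T1	0	1
Sphingobium	Sphingobium lactosutens DS20	2	1	T1	0	0
Sphingobium	Sphingobium sp. ANT17	1	0		0	0
Sphingobium	Sphingobium sp. AP49	1	0		0	0
Sphingobium	Sphingobium sp. DC-2	0	0		0	1
Sphingobium	Sphingobium sp. HDIP04	0	1	T4	1	1
Sphingobium	Sphingobium sp. KK22	1	1	T3	2	0
Sphingobium	Sphingobium sp. SYK6	2	1	T1	0	1
Sphingobium	Sphingobium sp. YL23	0	1	T3	0	0
Sphingobium	Sphingobium xenophagum QYY	0	1	T2	0	1
Sphingobium	Sphingobium yanoikuyae ATCC 51230	2	0		1	5
Sphingobium	Sphingobium yanoikuyae B1	2	0		0	1
Sphingomonas	Sphingomonas elodea ATCC 31461	0	0		0	1
Sphingomonas	Sphingomonas paucimobilis EPA505	2	0		0	1
Sphingomonas	Sphingomonas sp. KC8	1	0		0	0
Sphingomonas	Sphingomonas sp. MM1	0	1	T6	0	0
Sphingomonas	Sphingomonas sp. PAMC 26617	0	0		0	1
Sphingomonas	Sphingomonas sp. PAMC 26621	0	0		0	1
Sphingomonas	Sphingomonas sp. S17	0	0		0	1
Sphingomonas	Sphingomonas sp. SKA58	1	1	T1	0	0
Sphingomonas	Sphingomonas sp. UNC305MFCOL5.2	1	0		0	0
Sphingomonas	Sphingomonas sp. YL-JM2C	2	0		0	2
Sphingomonas	Sphingomonas wittichii RW1	0	0		0	3
Sphingopyxis	Sphingopyxis alaskensis RB2256	2	0		0	0
Sphingopyxis	Sphingopyxis sp. LC363	1	0		0	0
Sphingopyxis	Sphingopyxis sp. LC81	2	0		0	0
Sphingopyxis	Sphingopyxis sp. MC1	1	0		0	0
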