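name	group_key	period_key	category
Chlordecone	g00100	p0	pop
Methamidophos	g00101	p0	pesticide
PFOS	g01100	p0	pop
Metamitron	g10000	p0	pesticide
BDE-99	g10000	p0	pop
Metoxuron	g10000	p0	phenylurea
Monuron	g10000	p0	phenylurea
Diuron	g10000	p0	phenylurea
Linuron	g10000	p0	phenylurea
Buturon	g10000	p0	phenylurea
Chlorotoluron	g10000	p0	phenylurea
Daimuron	g10000	p0	phenylurea
Fenuron	g10000	p0	phenylurea
Methyldimuron	g10000	p0	phenylurea
Fluometuron	g10000	p0	phenylurea
Siduron	g10000	p0	phenylurea
Neburon	g10000	p0	phenylurea
Isoproturon	g10000	p0	phenylurea
Pencycuron	g10000	p0	phenylurea
Carbendazim	g10001	p0	pesticide
Metolachlor	g10001	p0	pesticide
Metazachlor	g10001	p0	phenylurea
Amidosulphuron	g10100	p0	sulphonylurea
Bensulphuron-methyl	g10100	p0	sulphonylurea
Chlorimuron-ethyl	g10100	p0	sulphonylurea
Cinosulphuron	g10100	p0	sulphonylurea
Ethametsulphuron-methyl	g10100	p0	sulphonylurea
Metsulphuron-methyl	g10100	p0	sulphonylurea
Nicosulphuron	g10100	p0	sulphonylurea
Oxasulphuron	g10100	p0	sulphonylurea
Pyrazosulphuron-ethyl	g10100	p0	sulphonylurea
Thifensulphuron-methyl	g10100	p0	sulphonylurea
Tribenuron-methyl	g10100	p0	sulphonylurea
Trifloxysulphuron-Na	g10100	p0	sulphonylurea
Triflusulphuron-methyl	g10100	p0	sulphonylurea
Rimsulphuron	g10100	p0	sulphonylurea
Iodosulphuron	g10100	p0	sulphonylurea
Carbetamide	g11000	p0	pesticide
Prometryne	g11000	p0	pesticide
Lindane	g11000	p0	pop
Pentachlorobenzene	g11000	p0	pop
Thiabendazole	g11001	p0	pesticide
Pyrimethanil	g11001	p0	pesticide
Cyprodinil	g11001	p0	pesticide
Carbofuran	g11001	p0	pesticide
TPP	g11100	p0	pesticide
Flazasulphuron	g11100	p0	sulphonylurea
Triasulphuron	g11100	p0	sulphonylurea
Azimsulphuron	g11100	p0	sulphonylurea
Chlorsulphuron	g11100	p0	sulphonylurea
Chlorfenvinphos	g11100	p1	pop
Diazinone	g11110	p0	pesticide
Pyrazophos	g11111	p0	pesticide
Chlorpyrifos	g11111	p1	pesticide
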