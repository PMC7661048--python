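locus_id	amino_acid	anticodon	sequence	start	end	strand	canonical
alaTGC-1	Ala	UGC	UCUAGCGUUUCGGGUGGGGGUCUUGGGCUUAACUGCACGCGCCUGGCCUGAGGCACAUUAGGCUGGCCCUGAUCCA	25000	25075	+	True
alaTGC-2	Ala	UGC	UCUAGCGUUUCGGGUGGGGGUCUUGGGCUUAACUGCACGCGCCUGGCCUGAGGCACAUUAGGCUGGCCCUGAUCCA	122543	122618	+	True
alaTGC-3	Ala	UGC	UCUAGCGUUUCGGGUGGGGGUCUUGGGCUUAACUGCACGCGCCUGGCCUGAGGCACAUUAGGCUGGCCCUGAUCCA	220086	220161	-	True
alaTGC-4	Ala	UGC	UCUAGCGUUUCGGGUGGGGGUCUUGGGCUUAACUGCACGCGCCUGGCCUGAGGCACAUUAGGCUGGCCCUGAUCCA	317629	317704	+	True
alaGGC	Ala	GGC	AUGUUAAGAUCUAACGGCUUUAACACGAGUCGUGGCUCGAACAAGUAAAGCCUGUAUGGGCGAUCGAUAGCUACCA	415172	415247	+	True
argACG-1	Arg	ACG	GCGUCCUCUAUGACUAGCUACUUAAUGUCGUCCACGAUGAUACGGAGUACCUACCGUCCUGUCAGACACUCAUCCA	512715	512790	-	True
argACG-2	Arg	ACG	GCGUCCUCUAUGACUAGCUACUUAAUGUCGUCCACGAUGAUACGGAGUACCUACCGUCCUGUCAGACACUCAUCCA	610258	610333	+	True
argCCG	Arg	CCG	GAUGUUAGUGCCCGUUAGUGAUAUGAGCCUAUGCCGCUACCUGAAUCUUGAUGCACAGCUCUAUUGCUCGCCUCCA	707801	707876	+	True
argTCT	Arg	UCU	CUCAUAGAAGUCUGCAGACCACCUAAAACGCCAUCUCGAUAUUGCGGUCGGAACUCACCUAGAUGGCAAUUACCCA	805344	805419	-	True
argCCT	Arg	CCU	GGCAUAAAACAGGACGUUGAGGCCAGAAGAUUACCUGAGUGUCAAUUCUCUACUCUCUUCCUCUUUGUAACUACCA	902887	902962	+	True
asnGTT-1	Asn	GUU	UGACCCCGUUUGUUGACGUGUUGGAGAGCAUAUGUUCGCGUGGUAGCACACGGACCCGUACCUUACAGAUAACCCA	1000430	1000505	+	True
asnGTT-2	Asn	GUU	UGACCCCGUUUGUUGACCUGUUGGAGAGCAUAUGUUCGCGUGGUAUCACACGGACCCGUACCUUACAGAUAACCCA	1097973	1098048	-	True
aspGTC-1	Asp	GUC	UCAGAGAUCUGUUGGGGUUCCGUAGAUGUACGUGUCCGUCGGCUCCCCCUAAUGAGUACAAAGAGCCUACGCGCCA	1195516	1195591	+	True
aspGTC-2	Asp	GUC	UCAGAGAUCUGUUGGGGUUCCGUAGAUGUACGUGUCCGUCGGCUCCCCCUAAUGAGUACAAAGAGCCUACGCGCCA	1293059	1293134	+	True
aspGTC-3	Asp	GUC	UCAGAGAUCUGUUGGGGUUCCGUAGAUGUACGUGUCCGUCGGCUCCCCCUAAUGAGUACAAAGAGCCUACGCGCCA	1390602	1390677	-	True
aspGTC-4	Asp	GUC	UCAGAGAUCUGUUGGGGUUCCGUAGAUGUACGUGUCCGUCGGCUCCCCCUAAUGAGUACAAAGAGCCUACGCGCCA	1488145	1488220	+	True
cysGCA	Cys	GCA	CGUGCUAACCCACCAUAUGUGUAUACAAGAUACGCACGAUCCGAAAUGAACAAGGAAUGCGAUAAUGCACACGCCA	1585688	1585763	+	True
glnTTG	Gln	UUG	GAGGAUCGGACUAUGCAGUUGUUCUGUGGAUACUUGGAUAGAAGUUAGUGUUGGGUUAAUGCGUCAAGCCCUCCCA	1683231	1683306	-	True
glnCTG	Gln	CUG	GCCACGCUAGAAAGUGGGAUUUCAGAAGUGCUGCUGCGAGGCAUAUUGCGCGAGCGUACGGUGAUAAUGAUAACCA	1780774	1780849	+	True
gluTTC-1	Glu	UUC	AAAUCCAAAUACAACUAGUACUUGUGGCAUACUUUCUUCAGUUUCAGGUCUGUCUGACCCAACUACGGCAUCGCCA	1878317	1878392	+	True
gluTTC-2	Glu	UUC	AAAUCCAAAUACAACUAGUACUUGUGGCAUACUUUCUUCAGUUUCAGGUCUGUCUGACCCAACUACGGCAUCGCCA	1975860	1975935	-	True
gluTTC-3	Glu	UUC	AAAUCCAAAUACAACUAGUACUUGUGGCAUACUUUCUUCAGUUUCAGGUCUGUCUGACCCAACUACGGCAUCGCCA	2073403	2073478	+	True
glyGCC-1	Gly	GCC	AAGUUAUAGCACGCGGCGGUCACUAAUAAGUGUGCCACGCUAUUGUUGCCUGGUCAGUCAAUUCUCACCCAAACCA	2170946	2171021	+	True
glyGCC-2	Gly	GCC	AAGUUAUAGCACGCGGCGGUCACUAAUAAGUGUGCCACGCUAUUGUUGCCUGGUCAGUCAAUUCUCACCCAAACCA	2268489	2268564	-	True
glyGCC-3	Gly	GCC	AAGUUAUAGCACGCGGCGGUCACUAAUAAGUGUGCCACGCUAUUGUUGCCUGGUCAGUCAAUUCUCACCCAAACCA	2366032	2366107	+	True
glyGCC-4	Gly	GCC	AAGUUAUAGCACGCGGCGGUCACUAAUAAGUGUGCCACGCUAUUGUUGCCUGGUCAGUCAAUUCUCACCCAAACCA	2463575	2463650	+	True
glyGCC-5	Gly	GCC	AAGUUAUAGCACGCGGCGGUCACUAAUAAGUGUGCCACGCUAUUGUUGCCUGGUCAGUCAAUUCUCACCCAAACCA	2561118	2561193	-	True
glyTCC	Gly	UCC	CUGCGCCGUGUCGCCGUAUUCACUGUUAACGCCUCCAUACGAAUAGACUAUGCCGCCCAUACUGGUAAUCAGGCCA	2658661	2658736	+	True
glyCCC	Gly	CCC	UCGGUGCACGCCCCUCUGGAAUGGUAUCGAAGUCCCAUUUUUAAUUCCAAUACGGUCAUGUGACACGCUGUUGCCA	2756204	2756279	+	True
hisGTG	His	GUG	UUAAUAAUCCGUUGGAGGAGACCCGCAACGCAGGUGUGUAUAGACGUUCGUUGGCUGAACCGGGUAGCCAGAUCCA	2853747	2853822	-	True
ileGAT-1	Ile	GAU	UUCAUUGGUUCAACAACGACAUGAGAGCUGGGCGAUCGGACGCUACCGUCCCGCUUGAAAACCCUAACCAUCACCA	2951290	2951365	+	True
ileGAT-2	Ile	GAU	UUCAUUGGUUCAACAACGACAUGAGAGCUGGGCGAUCGGACGCUACCGUCCCGCUUGAAAACCCUAACCAUCACCA	3048833	3048908	+	True
ileGAT-3	Ile	GAU	UUCAUUGGUUCAACAACGACAUGAGAGCUGGGCGAUCGGACGCUACCGUCCCGCUUGAAAACCCUAACCAUCACCA	3146376	3146451	-	True
ileGAT-4	Ile	GAU	UUCAUUGGUUCAACAACGACAUGAGAGCUGGGCGAUCGGACGCUACCGUCCCGCUUGAAAACCCUAACCAUCACCA	3243919	3243994	+	True
ile2CAT	Ile2	CAU	CCGUCGUUAUGCAGAUGUUAAUGGCUGAUCCCACAUUUCUUUACAGUGAGCCGCGCAUUAGUAAUACAACGAGCCA	3341462	3341537	+	True
leuTAA	Leu	UAA	GCCCCUUUACCGCUUUCGGGUGAAGGCCACUCCUAAACUGGGUCAGUCUCAAGCCUCCGCGUGUCUGUUCAACCCA	3439005	3439080	-	True
leuCAA	Leu	CAA	UUACGAGCGAGCCGUGGCUGAUCCGCUAGCACCCAAACUUUAAGACACAGCAUUAACAGGGUUGGUGCCCAACCCA	3536548	3536623	+	True
leuGAG-1	Leu	GAG	UGUCUCGAAACGAAGGGUAUUCACACUAACCGGGAGCUAGCUGCGGCACCCAGGUCAGAUCUAUACGGACGCACCA	3634091	3634166	+	True
leuGAG-2	Leu	GAG	UGUCUCGAAACGAAGGGUAUUCACACUAACCGGGAGCUAGCUGCGGCACCCAGGUCAGAUCUAUACGGACGCACCA	3731634	3731709	-	True
leuTAG	Leu	UAG	GGGAACGGAUGUUCGUUCGUCGGGUGCGGAAGAUAGUGGUGAAACACAUGCGCGCGAUGCCUCGUACGUUUACCCA	3829177	3829252	+	True
leuCAG	Leu	CAG	UCACCUUUUAAAAUGGCCAGACAGGCGAGCACGCAGAGUAGGGAUGGAAAUUAUCGUUUACUCGCUGCAAUCCCCA	3926720	3926795	+	True
lysTTT-1	Lys	UUU	GGCGCGGUAGGGAACACGUGACGCAAUUUUAGAUUUGCUAAUCCAGGUGCCGUCCGUUCUUGCGUGAACCAACCCA	4024263	4024338	-	True
lysTTT-2	Lys	UUU	GGCGCGGUAGGGAACACGUGACGCAAUUUUAGAUUUGCUAAUCCAGGUGCCGUCCGUUCUUGCGUGAACCAACCCA	4121806	4121881	+	True
metCAT-1	Met	CAU	GAGAAGUGAACAAAGGUGGGUAUUCCUACUGCUCAUGUCAGAGCAUGCGCCCAAUGUUGAUUAUGAUGAAUUACCA	4219349	4219424	+	True
metCAT-2	Met	CAU	GAGAAGUGAACAAAGGUGGGUAUUCCUACUGCUCAUGUCAGAGCAUGCGCCCAAUGUUGAUUAUGAUGAAUUACCA	4316892	4316967	-	True
fmetCAT-1	fMet	CAU	GUCAGCCGUUCGAGGUCCUCGUAAGGUAAUCUCCAUUCCCCCUUUCGACCGAAGGGUUAGUGCAUGUUAGCAUCCA	4414435	4414510	+	True
fmetCAT-2	fMet	CAU	GUCAGCCGUUCGACGUCCUCGUAAGGUAAUCUCCAUUCCCCCUUUCGACCGAAGGGUUAGUGCAUGUUAGCCUCCA	4511978	4512053	+	True
fmetCAT-3	fMet	CAU	GUCAGCCGUUCGAGGUCCUCGUAAGGUAAUCUCCAUUCCCCCUUUCGACCGAAGGGUUAGUGCAUGUUAGCAUCCA	4609521	4609596	-	True
pheGAA	Phe	GAA	GCUUCCCUAGCGGAGAGUGGCAGCAGGGGUAGUGAAAUGACGUGGUUGGGCCGAUUAGUCACCGAUAUCUGACCCA	4707064	4707139	+	True
proTGG	Pro	UGG	ACCCCAUAGUUUUGCGUUUCAGGAGUGAUCGAAUGGUCAACCGAGUAUAACGGCCUGACAAUCCGUUUCGGAACCA	4804607	4804682	+	True
proGGG	Pro	GGG	UACGCAAAAGGAUCUUUAGGCCUGUCUACUGUCGGGUUAGACAGUGUCGUUGUGGCUUCCGACUUUCCACAGUCCA	4902150	4902225	-	True
serGGA	Ser	GGA	AUUAGUUUACUCGGUUAUGCGAUCAAAAGGGGCGGACGAUCGCUCAAAAUUUCCUUGCAGAAUCGGAAUCGUUCCA	4999693	4999768	+	True
serTGA	Ser	UGA	CAAGUGUCUAUACGUCUGGGGUAUAACGUGUUUUGAUGUAGUCUUCGCGCUCUCCCUGACUCACAUAGUCUAUCCA	4150000	4150075	+	True
serCGA	Ser	CGA	CAUCGCGCAGAUAGCGGGAAGGGAUGUUUCGUCCGAACGCCAAACGAUUUAAGCCCCAGAUAUGGGUCCUACGCCA	1624957	1625032	+	True
serGCT	Ser	GCU	ACACUUAGUUCGCCACGAAAGAUAUCGUUAUGCGCUUGUCAUGUGCGUCAAGUUCAACCAAGAGCUCUUUGUACCA	5097236	5097311	+	True
thrTGT	Thr	UGU	AUUAUUUAUUACGCGACGACAGACCACUACGGCUGUUUCUAACUUAGAUCCACCAAAAGUGUUGAGGGAAGUCCCA	5194779	5194854	-	True
thrGGT-1	Thr	GGU	GACUCCACCGUUUUCCCUGUUGACCCUCAUGCCGGUUCUCUGUCGCAGUGGGAACCACCAAAGCUCUGCCUCCCCA	5292322	5292397	+	True
thrGGT-2	Thr	GGU	GACUCCACCGUUUUCCCUGUUGACCCUCAUGCCGGUUCUCUGUCGCAGUGGGAACCACCAAAGCUCUGCCUCCCCA	5389865	5389940	+	True
trpCCA	Trp	CCA	UAAUAUCGGCUAUUUGAUAGAUUUAAGGAAUCGCCAGAAAGUCAAUCGGCUAUCGGUGUCUGCUCAUCUACGCCCA	5487408	5487483	-	True
tyrGTA	Tyr	GUA	UUUAGUCGAGUCCACCCAGAAUUAGGGGUUCUCGUAUGGUUCCCUUUGCCUAUGCAGCAUCAGCUCUCUUUAGCCA	5584951	5585026	+	True
valTAC-1	Val	UAC	UCAAAUCCUUACUGGAUGAUUUGAGACAUUGAAUACACCGUAUCCGAUCCCUCCUAGGCUAACAUGCGUGCCGCCA	5682494	5682569	+	True
valTAC-2	Val	UAC	UCAAAUCCUUACUGGAUGAUUUGAGACAUUGAAUACACCGUAUCCGAUCCCUCCUAGGCUAACAUGCGUGCCGCCA	5780037	5780112	-	True
valTAC-3	Val	UAC	UCAAAUCCUUACUGGAUGAUUUGAGACAUUGAAUACACCGUAUCCGAUCCCUCCUAGGCUAACAUGCGUGCCGCCA	5877580	5877655	+	True
valTAC-4	Val	UAC	UCAAAUCCUUACUGGAUGAUUUGAGACAUUGAAUACACCGUAUCCGAUCCCUCCUAGGCUAACAUGCGUGCCGCCA	5975123	5975198	+	True
valGAC-1	Val	GAC	AGCAGAUAGAUUGUAAGAGUGUACUCACCCAAGGACAGGAGGCUCCCUGGUCCCAUACAAGGGAGCGCCUUCGCCA	6072666	6072741	-	True
valGAC-2	Val	GAC	AGCAGAUAGAUUGUAAGAGUGUACUCACCCAAGGACAGGAGGCUCCCUGGUCCCAUACAAGGGAGCGCCUUCGCCA	6170209	6170284	+	True
cysGCA-2	Cys	GCA	GAUGGUUAGCGUAAACUGUAGAUAUGGAUACUAGCAGGAGAGCUAGGAGCUGAGCCAUAGCGGAUUAAUCAACCCA	5910011	5910086	-	False
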