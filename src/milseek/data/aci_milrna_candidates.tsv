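lib	accession	contig_id	sequence	reads
F	aci-milR-1	FB_M2436	UACCCGACUGGAGGACGAGAUU	79
F	aci-milR-2a-1	FB_M2455	CUGCGAUGGAUGACUGCGACGACGAU	523
F	aci-milR-2a-3	FB_M2455	CCGCGAUGGAUGACUGCGACGA	182
F	aci-milR-2a-4	FB_M2455	CUGCGGUGGAUGACUGCGACGA	260
F	aci-milR-2a-10	FB_M2455	CUGCGAUAGAUGACUGCGACGACG	12
F	aci-milR-2a-13	FB_M2455	CUGCGAUGGAUGACUGCGACGACGC	88
F	aci-milR-2a-15	FB_M2455	CGUUGUUGUCAGUUGUACAUCGCACU	19
F	aci-milR-2b-2	FB_M2455	UCGUUGUUGUCAGUUGUACAUCG	109
F	aci-milR-2b-3	FB_M2455	UCGUUGUUGUCAGUUGUACAUCGCA	61
F	aci-milR-2b-4	FB_M2455	UCGUUGUUGUCAGUUGUACAUCGCAC	34
F	aci-milR-2b-6	FB_M2455	GUUGUUGUCAGUUGUACAUCGCACU	57
F	aci-milR-2b-7	FB_M2455	CGUUGUUGUCAGUUGUACAUCGCACU	30
F	aci-milR-2b-8	FB_M2455	GUUGUUGUCAGUUGUACAUCGCACUA	42
M	aci-milR-3a-1	FB_M4358	GAAACGGACGUCAGGACCAG	20
M	aci-milR-3a-2	FB_M4358	GCGAAACGGACGUCAGGACCAGA	11
M	aci-milR-3a-3	FB_M4358	AGCGAAACGGACGUCAGGACCAA	51
B	aci-milR-3b-1	FB_M4358	CGGUCCUGGACGUCCGUUUACGC	2169
F	aci-milR-3b-5	FB_M4358	CGGUCCUGGACGUCCGUUUACG	900
F	aci-milR-3b-6	FB_M4358	GUCCUGGACGUCCGUUUACGCA	87
F	aci-milR-3b-8	FB_M4358	CGGUCCUGGGCGUCCGUUUACGC	13
M	aci-milR-4	FB_M4900	UGCGAUCGGACUUUUUGGAA	31
F	aci-milR-5	FB_M7084	AAGAAUAGCAAAGAGUGAACAG	53
F	aci-milR-6a-1	FB_M7816	AUCGGCAGCGUAUGGGGAUGAUG	849
F	aci-milR-6a-3	FB_M7816	AUCGGCAGCGUAUGGGGAUGAUGC	39
F	aci-milR-6b-1	FB_M7816	CGCGAUCCUCAUGCGCUGUCGA	592
F	aci-milR-6b-3	FB_M7816	CGCGAUCCUCAUGCGCUGUCGAU	19
F	aci-milR-6b-5	FB_M7816	CGAUCCUCAUGCGCUGUCGAUGC	211
F	aci-milR-6b-7	FB_M7816	CGAUCCUCAUGCGCUGUCGAUGCA	17
F	aci-milR-7-3	FB_M8066	CAUCUAUGUUAAGCUAAUUGGCUUUAGUU	14
M	aci-milR-9	FB_M9694	UGGCUUCUCUCUAUCCUCGCAG	10
M	aci-milR-10-1	FB_M11279	UCUGGGUUCUUCCUCUCAUAUGA	35
M	aci-milR-10-2	FB_M11279	UCUGGGUUCUUCCUCUCAUAUGU	27
F	aci-milR-11	FB_M13321	UUCCAUCAGCUUCUUGUAAGGCU	47
F	aci-milR-12	FB_M13515	GGUCUUUCUUUGGUGAUACGAGA	21
M	aci-milR-13	FB_M15202	CAUUAGUUAAUAGGAUCAAGAC	12
F	aci-milR-14a-2	FB_M19318	GUCCAGGGGGCCCCUCAGUAUC	13
F	aci-milR-14a-3	FB_M19318	GGUCCAGGGGGCCCCUCAGUAUC	25
B	aci-milR-14b-1	FB_M19318	UACUGAGGGGUCGUCUAGACAGA	25
F	aci-milR-14b-2	FB_M19318	UACUGAGGGGUCGUCUAGACAGU	9624
M	aci-milR-15a-1	FB_M20087	CCUUUAUCGUCUUUUUACUUAUUCAAUG	25
F	aci-milR-15a-3	FB_M20087	CCUUUAUCGUCUUUUUACUUAUU	53
M	aci-milR-15b-1	FB_M20087	GACAUUGUGAAAAGACAUAGAGGGU	38
F	aci-milR-15b-2	FB_M20087	UUGUGAAAAGACAUAGAGGGUG	43
F	aci-milR-15b-3	FB_M20087	UGACAUUGUGAAAAGACAUAGAGGG	42
F	aci-milR-15b-4	FB_M20087	UUUGACAUUGUGAAAAGACAUAGAGG	22
B	aci-milR-15c-1	FB_M20087	UAUCGAUCCUUUAGUCCCUC	14
F	aci-milR-16-2	FB_M24188	AGGAUGCUUACGAAUACGAUGGA	12
M	aci-milR-17a-1	FB_M28577	UCUGAUUGUCUUCCUUCUCAUGG	30
M	aci-milR-17a-2	FB_M28577	UCUGAUUGUCUUCCUUCUCAUGGAC	27
F	aci-milR-17a-3	FB_M28577	UCUGAUUGUCUUCCUUCUCAUGGA	16
B	aci-milR-17b-1	FB_M28577	UACCAUGAGAAUGGAAGAUGCUCAGA	53
F	aci-milR-17b-2	FB_M28577	UACCAUGAGAAUGGAAGAUGCUCA	55
F	aci-milR-17b-3	FB_M28577	CAUGAGAAUGGAAGAUGCUCAGACC	26
F	aci-milR-17c-1	FB_M28577	AAGUACCAGAGCACAGUCCAUGA	200
F	aci-milR-17c-2	FB_M28577	AAGUACCAGAGCACAGUCCAUGAG	21
F	aci-milR-18	FB_M33490	UUGCGUUCGACUUGUUCUCCC	105
M	aci-milR-19a-1	FB_M33646	ACCUCUAGUGCAGGUCACAUACU	114
F	aci-milR-19a-2	FB_M33646	CACCUCUAGUGCAGGUCACAUACU	14
F	aci-milR-19b	FB_M33646	UAUGUGACCUACAAUAGAGGUGC	13
F	aci-milR-20	FB_M36986	CGUUUGGCUCGUCUCUUCGUGCUCU	311
F	aci-milR-21-1	FB_M47647	GUAAAGUUAAGAUGAAUUAAAGC	13
F	aci-milR-21-2	FB_M47647	UGUAAAGUUAAGAUGAAUUAAAGC	13
F	aci-milR-21-3	FB_M47647	AAAGUUAAGAUGAAUUAAAGCUAGA	13
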