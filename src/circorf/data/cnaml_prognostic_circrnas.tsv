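gene	chr	start	end	annotation	de_flag
ABHD2	chr15	89113724	89116521	C-term|canonicalMet	0
ANKRD12	chr18	9182381	9221999	C-term|canonicalMet|conservedStructure	1
ARAP2	chr4	36228581	36229645	C-term|canonicalMet|lackingDomain	1
CLNS1A	chr11	77619605	77625818	canonicalSTOP|conservedStructure|internalMet	0
CPSF6	chr12	69251128	69262562	canonicalSTOP|conservedStructure|internalMet	0
CSNK1G3	chr5	123545416	123557564	C-term|canonicalMet	0
FBXW7	chr4	152411302	152412529	C-term|canonicalMet	0
HIPK3	chr11	33286412	33287511	C-term|canonicalMet|conservedStructure	1
KLHL8	chr4	87195323	87195690	C-term|canonicalMet	0
MGA	chr15	41668827	41669958	C-term|canonicalMet|lackingDomain	0
NCOA2	chr8	70213902	70216764	C-term|canonicalMet|novelDomainStructure	1
OMA1	chr1	58506059	58539310	C-term|canonicalMet|conservedStructure	0
PCMTD1	chr8	51860844	51861246	C-term|canonicalMet|conservedStructure	0
PDE3B	chr11	14771936	14789242	C-term|internalMet	0
RELL1	chr4	37631384	37638504	canonicalSTOP|internalMet	0
RNF13	chr3	149846010	149921227	C-term|canonicalMet|conservedStructure	1
RNF220	chr1	44411980	44412722	C-term|canonicalMet	0
RSRC1	chr3	158122102	158123991	C-term|canonicalMet	0
SATB1	chr3	18378169	18420991	C-term|canonicalMet|lackingDomain	1
SHOC2	chr10	110964124	110985765	lackingDomain	0
SLC38A1	chr12	46229152	46243314	C-term|canonicalMet|conservedStructure	0
SLC8A1	chr2	40428472	40430304	C-term|canonicalMet|conservedStructure	1
XPO1	chr2	61522610	61533903	C-term|canonicalMet|conservedStructure	1
ZBTB44	chr11	130260855	130261929	C-term|canonicalMet|lackingDomain	0
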