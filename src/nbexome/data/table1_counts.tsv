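gene	case_with	case_without	1000g_ita_with	1000g_ita_without	1000g_eur_with	1000g_eur_without	house_ita_with	house_ita_without
BARD1	4	100	0	107	0	396	0	106
AXIN2	4	48	0	107	3	393	1	105
MC1R	5	47	5	102	3	393	3	103
CHEK2	3	49	0	107	3	393	0	106
SLC25A13	2	50	0	107	2	394	0	106
CD96	1	51	0	107	1	395	0	106
FH	1	51	0	107	0	396	1	105
XRRC3	1	51	0	107	1	395	0	106
APC	2	50	2	105	7	389	1	105
RAD50	1	51	0	107	2	394	2	104
BRCA2	1	51	1	106	3	393	1	105
SLX4	1	51	0	107	5	391	0	106
FANCM	1	51	1	106	3	393	3	103
PALB2	1	51	5	102	2	394	2	104
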