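gene	cancer_type	role	recurrent_sites
PIK3CA	breast	oncogene	542,545,1047
AKT1	breast	oncogene	17
MYC	breast	oncogene
FGFR2	breast	oncogene	549
ESR1	breast	oncogene	536,537,538
ARID1B	breast	tsg
SPEN	breast	tsg
TP53	breast	tsg
NSD1	biliary	tsg
ARID1A	biliary	tsg
KRAS	biliary	oncogene	12,13,61
TP53	biliary	tsg
EGFR	lung	oncogene	746,790,858
KRAS	lung	oncogene	12,13,61
TP53	lung	tsg
ESR1	breast	census
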