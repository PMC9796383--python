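gene_symbol	monogenic_citations	ge_fdr
AP3D1	5	0.001574
CAMTA1	2	0.002134
SCN1A	290	0.003081
SETD1A	3	0.011449
STX1B	8	0.021646
RAPGEF2	4	0.028498
UBTF	2	0.031009
GABRA2	9	0.032305
PCDH7	1	0.033095
RIMS1	1	0.033095
PHACTR1	2	0.03322
RBFOX1	5	0.037034
TTC21B	2	0.038402
MMP27	1	0.043774
DOC2A	1	0.047941
GRM4	4	0.049296
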