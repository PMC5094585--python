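gene	localization	n_blocks	n_haplotypes	n_haplotypes_freq_gt05	n_tagged_freq_gt05	snps
DOCK7	1p31.3	1	9	4	4	rs10493326; rs1168026; rs11577840; rs13375691; rs17381383; rs4915846; rs11207998; rs7419069; rs12117388; rs912540
DCTN1	2p13	1	3	2	1	rs9309484
GOLGB1	3q13	1	10	8	8	rs9968051; rs9819530; rs9852845; 6803839; rs11927625; rs10049460; rs10470410; rs1919555; rs1919554; rs12498138
PRR16	5q23.1	13	63	42	28	rs7715549; rs4895255; rs2601208; rs2601209; rs2655069; rs2655066; rs2691100; rs7710848; rs921782; rs4895160; rs1159767; rs1524558; rs9327147; rs12523269; rs6862090; rs13161840; rs300974; rs300970; rs13174421; rs2077726; rs11241254; rs17427447; rs6865072; rs1524565; rs1375462; rs1584465; rs985263; rs12514071; rs12519395; rs10042938; rs2218717; rs17428689; rs1466107; rs1449142; rs7736461; rs716815; rs12187844; rs10519647; rs4895272
ANKHD1	5q31.3	1	9	8	1	rs1432959; rs10042299; rs3733681; rs1835959; rs9324644
TRIM41	5q35.3	1	6	5	3	rs2545098; rs7727787; rs2770957; rs2261114
CHMP5	9p13.3	2	5	5	5	rs831271; rs831276; rs831275
SDCCAG3	9q34.3	3	15	9	9	rs1132005; rs3812578; rs10706; rs4298601; (rs10870446)
C10orf67	10p12.2	3	10	8	8	rs10828426; rs11013389; rs4259746; rs10828431; rs2036921
VIM	10p13	1	8	5	3	rs3758413; rs7914640; rs11254468; rs1980662
IKBIP	12q23.1	2	11	11	6	rs1048906; rs1055656; rs17028572; rs4762501; rs12371097; rs1281083
KRT15	17q21.2	1	5	3	3	rs2662; rs2305556; rs3744784; rs3760519
PPP1R12C	19q13.42	1	6	5	5	rs7259963; rs604216
LDOC1	Xq27	1	7	3	3	rs710106; rs4824993
PPP2R3B	Xp22.33; Yp11.3	2	9	7	1	rs2738319
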