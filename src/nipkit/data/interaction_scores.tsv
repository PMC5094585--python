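protein	y2h	y2h_plus	coip	bret	total
RICK	20	+	20	20	60
ANKHD1	10	+	20	10	40
CHMP5	20	+	0	20	40
SDCCAG3	15	+	15	10	40
LDOC1	10	+	20	10	40
TRIM41	20	+	10	10	40
PPP1R12C	15	+	5	10	30
KRT15	15		10	0	25
C10ORF67	15		0	10	25
VIMENTIN	10		10	0	20
DOCK7	10		0	10	20
PPP2R3B	5	+	0	10	15
IKBIP	15		0	0	15
PRR16	5		0	0	5
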