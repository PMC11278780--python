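strain	host	location	mtAC	mtBA	ppzA-A1	ppzA-T1	ppzA-C	ppzA-A2	ppzA-M	ppzA-T2	ppzA-R	ppzA-dR	dmaW	easF	easC	easE	easD	easA	easG	cloA	lpsB	lpsA	easH	lpsC	easO	easP	idtG	idtB	idtM	idtC	idtS	idtP	idtQ	idtF	idtK	idtE	idtJ	lolC	lolF	lolD	lolT	lolU	lolA	lolO	lolP	lolE	lolN	lolM
ADX8	Elymus cylindricus	Hongyuan	+	-	+	+	+	+	+	+	+	-	+	+	+	+	+	+	+	+	+	+	+	-	-	-	+	+	+	+	+	+	+	+	+	-	-	+	-	-	-	-	-	-	-	-	-	-
ADX12	Elymus cylindricus	Hongyuan	+	-	+	+	+	+	+	+	+	-	+	+	+	+	+	+	+	+	+	+	+	-	-	-	+	+	+	+	+	+	+	+	+	-	-	+	-	-	-	-	-	-	-	-	-	-
ADX9	Elymus cylindricus	Hongyuan	+	-	+	+	+	+	+	+	+	-	+	+	+	+	+	+	+	+	+	+	+	-	-	-	+	+	+	+	+	+	+	+	+	-	-	+	-	-	-	-	-	-	-	-	-	-
AD16	Elymus cylindricus	Hongyuan	+	-	+	+	+	+	+	+	+	-	+	+	+	+	+	+	+	+	+	+	+	-	-	-	+	+	+	+	+	+	+	+	+	-	-	+	-	-	-	-	-	-	-	-	-	-
FC1	Elymus sibiricus	Tumotezuo	+	-	+	+	+	+	+	+	-	+	+	+	+	+	+	+	+	+	+	+	+	-	-	-	+	+	+	+	+	-	+	+	+	-	-	+	-	-	-	-	-	-	-	-	-	-
FC4	Elymus sibiricus	Tumotezuo	+	-	+	+	+	+	+	+	-	+	+	+	+	+	+	+	+	+	+	+	+	-	-	-	+	+	+	+	+	-	+	+	+	-	-	+	-	-	-	-	-	-	-	-	-	-
LE6	Elymus dahuricus	Rangtang	+	-	+	+	+	+	+	+	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	+	-	-	-	-	-	-	-	-	-	-
LE1	Elymus dahuricus	Rangtang	+	-	+	+	+	+	+	+	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	+	-	-	-	-	-	-	-	-	-	-
LE3	Elymus dahuricus	Rangtang	+	-	+	+	+	+	+	+	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	+	-	-	-	-	-	-	-	-	-	-
LE7	Elymus dahuricus	Rangtang	+	-	+	+	+	+	+	+	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	+	-	-	-	-	-	-	-	-	-	-
GA7	Elymus nutans	Maqu	+	-	+	+	+	+	+	+	-	+	+	+	+	+	+	+	+	+	+	+	+	-	-	-	+	+	+	+	+	-	+	+	+	-	-	+	-	-	-	-	-	-	-	-	-	-
GA2	Elymus nutans	Maqu	+	-	+	+	+	+	+	+	-	+	+	+	+	+	+	+	+	+	+	+	+	-	-	-	+	+	+	+	+	-	+	+	+	-	-	+	-	-	-	-	-	-	-	-	-	-
AD3	Elymus cylindricus	Hongyuan	+	-	+	+	+	+	+	+	+	-	+	+	+	+	+	+	+	+	+	+	+	-	-	-	+	+	+	+	+	+	+	+	+	-	-	+	-	-	-	-	-	-	-	-	-	-
AD5	Elymus cylindricus	Hongyuan	+	-	+	+	+	+	+	+	+	-	+	+	+	+	+	+	+	+	+	+	+	-	-	-	+	+	+	+	+	+	+	+	+	-	-	+	-	-	-	-	-	-	-	-	-	-
GA4	Elymus nutans	Maqu	+	-	+	+	+	+	+	+	-	+	+	+	+	+	+	+	+	+	+	+	+	-	-	-	+	+	+	+	+	-	+	+	+	-	-	+	-	-	-	-	-	-	-	-	-	-
KE1	Elymus tangutorum	Rangtang	+	-	+	+	+	+	+	+	-	+	+	+	+	+	+	+	+	+	+	+	+	-	-	-	+	+	+	+	+	+	+	+	+	-	-	+	-	-	-	-	-	-	-	-	-	-
KEM1	Elymus tangutorum	Rangtang	+	-	+	+	+	+	+	+	-	+	+	+	+	+	+	+	+	+	+	+	+	-	-	-	+	+	+	+	+	+	+	+	+	-	-	+	-	-	-	-	-	-	-	-	-	-
KEM3	Elymus tangutorum	Rangtang	+	-	+	+	+	+	+	+	-	+	+	+	+	+	+	+	+	+	+	+	+	-	-	-	+	+	+	+	+	+	+	+	+	-	-	+	-	-	-	-	-	-	-	-	-	-
KEM4	Elymus tangutorum	Rangtang	+	-	+	+	+	+	+	+	-	+	+	+	+	+	+	+	+	+	+	+	+	-	-	-	+	+	+	+	+	+	+	+	+	-	-	+	-	-	-	-	-	-	-	-	-	-
LB1	Elymus dahuricus	Huachi	+	-	+	+	+	+	+	+	-	+	+	+	+	+	+	+	+	+	+	+	+	-	-	-	+	+	+	+	+	+	+	+	+	-	-	+	-	-	-	-	-	-	-	-	-	-
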