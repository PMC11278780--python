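location	altitude_m	longitude	latitude	host	n_samples	n_infected	n_strains
Rangtang	3571	33°24′02″	32°20′27″	Elymus tangutorum	28	8	4
Rangtang	3571	33°24′02″	32°20′27″	Elymus dahuricus	7	4	4
Hongyuan	3494	102°31′31″	33°16′41″	Elymus cylindricus	44	36	6
Tumotezuo	1150	111°34′00″	40°34′00″	Elymus sibiricus	12	2	2
Maqu	3600	102°39′20″	33°09′24″	Elymus nutans	12	1	3
Huachi	1337	107°45′32″	36°42′53″	Elymus dahuricus	6	4	1
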