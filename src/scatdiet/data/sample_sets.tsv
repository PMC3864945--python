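location	year	phase	n_collected	n_amplified	n_sexed
Casey Whitney Point	2008	Creche	64	58	48
Casey Blakeney Point	2008	Creche	34	32	26
Casey	2012	Creche	53	33	32
Davis	2012	Incubation	19	16	16
Davis	2012	Guard	26	18	17
Davis	2012	Creche	49	35	32
Mawson	2010	Guard	50	39	34
Mawson	2010	Creche	47	39	36
Mawson	2011	Guard	50	31	26
Mawson	2011	Creche	37	32	29
Mawson	2012	Guard	53	27	25
Mawson	2012	Creche	52	29	27
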