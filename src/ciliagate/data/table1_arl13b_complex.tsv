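symbol	name	tap_count	silac_enrichment
ARL13B	ADP-ribosylation factor-like 13B	31.2	10.4
IFT74	intraflagellar transport 74	13.3	5.0
IFT81	intraflagellar transport 81	11.0	4.6
CAND2	cullin-associated and neddylation-dissociated 2	9.0	6.4
TTC26	tetratricopeptide repeat domain 26	7.7	4.7
DCAF8	DDB1 and CUL4 associated factor 8	6.8	8.0
IPO9	importin 9	6.7	7.5
TNPO1	transportin 1	6.3	3.7
FANCD2	Fanconi anemia, complementation group D2	6.2	6.2
TELO2	Telomere maintenance 2	5.5	5.0
IFT27	intraflagellar transport 27	5.3	7.9
CAND1	cullin-associated and neddylation-dissociated 1	5.3	nd
IPO4	importin 4	5.3	6.7
XPO2	exportin 2	5.2	nd
XPO5	exportin 5	5.0	2.6
TTC30A	tetratricopeptide repeat domain 30A	4.5	2.1
IFT22	RAS oncogene family-like 5.	4.3	9.1
ATXN10	ataxin 10	4.3	4.2
MMS19	MMS19 nucleotide excision repair homolog	4.3	4.5
PEX19	peroxisomal biogenesis factor 19	4.2	12.3
ARMC6	armadillo repeat containing 6	4.2	5.3
IPO8	importin 8	4.0	4.5
WDR17	WD repeat domain 17	3.7	5.3
IFT52	intraflagellar transport 52	3.5	4.8
HLA-C	major histocompatibility complex, class I, C	3.5	3.3
IFT46	intraflagellar transport 46	3.3	6.5
DHCR7	7-dehydrocholesterol reductase	2.8	3.1
ANKRD13A	ankyrin repeat domain 13A	2.3	4.2
GEMIN4	gem associated protein 4	2.3	4.7
IPO5	importin 5	2.3	2.2
CCDC47	coiled-coil domain containing 47	2.2	5.2
NPEPPS	aminopeptidase puromycin sensitive	2.2	2.6
MDH2	malate dehydrogenase 2	2.0	nd
CNP	2′,3′-cyclic nucleotide 3′ phosphodiesterase	2.0	4.1
IFT25	intraflagellar transport 25	1.8	8.7
ARL1	ADP-ribosylation factor-like 1	1.8	5.7
NUBP2	nucleotide binding protein 2	1.8	6.5
AAR2	AAR2 splicing factor homolog	1.8	nd
FASTKD1	FAST kinase domains 1	1.8	5.7
HEATR3	HEAT repeat containing 3	1.8	4.3
TTC27	tetratricopeptide repeat domain 27	1.8	5.3
S100A7	S100 calcium binding protein A7	1.7	nd
RPLP1	ribosomal protein, large, P1	1.7	2.7
HBB	hemoglobin, beta	1.7	nd
SAAL1	serum amyloid A-like 1	1.7	8.1
SUCLA2	succinate-CoA ligase, ADP-forming, beta subunit	1.7	4.4
IPO7	importin 7	1.5	2.4
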