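sco_id	protein	function	ratio_dnad	ratio_dna
SCO5071	ActVI-A	Putative hydroxylacyl-CoA dehydrogenase	134.4	4.5
SCO5072	ActVI-1	Stereospecific ketoreductase	29.5	7.3
SCO5073	ActVI-2	Enoyl reductase	43.8	3.9
SCO5074	ActVI-3	Oxidoreductase	298.6	3.5
SCO5075	ActVI-4	Enoyl reductase	32.7	4.2
SCO5076	ActVA-1	MFS transporter
SCO5077	ActVA-2	Dimerization of a BIQ intermediate via C-C bond formation?	6.8	2.6
SCO5078	ActVA-3	Involved in C-6 hydroxylation	27.2	7.4
SCO5079	ActVA-4	Regiospecific dimerization via C-C bond formation	86.1	6.4
SCO5080	ActVA-5	Mono-oxygenase (requires ActVB)	37.9	5.2
SCO5081	ActVA-6	Hydroxylase	16.0	2.4
SCO5082	ActR	Repressor of actAB	3.6	2.7
SCO5083	ActII-2 (ActA)	Export pump	35.4	0.8
SCO5084	ActII-3 (ActB)	Export pump	24.1	1.9
SCO5085	ActII-4	Transcription activator	4.9	2.8
SCO5086	ActIII	Keto acyl reductase	38.7	5.2
SCO5087	ActI-1	PKS alpha subunit	19.9	6.4
SCO5088	ActI-2	PKS beta subunit	38.8	10.5
SCO5089	ActI-3	PKS acyl carrier protein	22.6	2.9
SCO5090	ActVII	Cyclase / dehydratase	5.9	10.0
SCO5091	ActIV	Cyclase-Thioesterase	12.3	2.6
SCO5092	ActVB	Oxidoreductase	7.3	3.3
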