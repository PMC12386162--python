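# Published primary Sjogren's syndrome prevalence estimates, per 100,000 adults.
population	country	prevalence	ci_low	ci_high	source
FIN	Finland	34.1	29.8	38.4	Kauppi et al., 1997
TSI	Italy	58.2	51.3	65.1	Baldini et al., 2014
IBS	Spain	52.7	45.8	59.6	Narvaez et al., 2020
GBR	UK	45.3	40.1	50.5	Bowman et al., 2004
CEU	N. Europe	42.8	38.2	47.4	Goransson et al., 2011
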