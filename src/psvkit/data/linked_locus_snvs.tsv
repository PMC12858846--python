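position	gene	cadd	fathmm_noncoding	fathmm_coding	remm	maf	splice_ai	classification
chr7:32696283A>G	DPY19L1P1	7.7	0.15598	0.00457	0.0845433			Low evidence
chr7:33096550T>A	RP9	24.8	0.95405	0.96568	0.994029			Deleterious
chr7:33769044T>A		3.0	0.17276	0.09343	0.567987			Low evidence
chr7:33969722A>G	BMPER	2.3	0.11395	0.01480	0.656556			Low evidence
chr7:34559955A>C	NPSR1-AS1	1.8	0.06174	0.00105	0.468994			Low evidence
chr7:34802348G>C	NPSR1	6.1	0.04398	0.00260	0.0654325			Low evidence
chr7:34901635A>G		1.1	0.08234	0.00702	0.0008333			Low evidence
chr7:34968054A>C	DPY19L1	4.1	0.12884	0.03363	0.002725			Low evidence
chr7:35062468G>A		3.2	0.06101	0.00333	0.198626			Low evidence
chr7:35120873C>A	DPY19L2P1	2.3	0.04602	0.00170	0.291211			Low evidence
chr7:35162505C>A	DPY19L2P1	0.4	0.07359	0.00501	0.0			Low evidence
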