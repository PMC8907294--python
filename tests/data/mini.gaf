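!gaf-version: 2.2
!generated synthetic fixture over the toy ontology
SYN	g1	g1	enables	GO:0000004	REF:1	IDA		F	name a	syn	protein	taxon:1	20200101	SYN		
SYN	g1	g1	enables	GO:0000005	REF:1	IEA		F	name b	syn	protein	taxon:1	20200101	SYN		
SYN	g1	g1	NOT|enables	GO:0000003	REF:1	IDA		F	name c	syn	protein	taxon:1	20200101	SYN		
SYN	g1	g1	involved_in	GO:9999999	REF:1	IDA		P	name p	syn	protein	taxon:1	20200101	SYN		
SYN	g2	g2	enables	GO:0000005	REF:1	IDA		F	name b	syn	protein	taxon:1	20200101	SYN		
SYN	g2	g2	enables	GO:0000104	REF:1	IEA		F	alt of a	syn	protein	taxon:1	20200101	SYN		
SYN	g3	g3	enables	GO:0000006	REF:1	IEA		F	name d	syn	protein	taxon:1	20200101	SYN		
SYN	g3	g3	enables	GO:0000099	REF:1	IDA		F	obsolete	syn	protein	taxon:1	20200101	SYN		
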