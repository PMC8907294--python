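GENE PRODUCT ID	GO TERM	GO ASPECT	GO EVIDENCE CODE	QUALIFIER
g1	GO:0000004	molecular_function	IDA	enables
g1	GO:0000006	F	IEA	enables
g2	GO:0000005	F	IEA	enables
g2	GO:0000002	F	IDA	NOT|enables
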