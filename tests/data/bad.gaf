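!gaf-version: 2.2
SYN	g1	g1	enables	GO:0000004
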