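format-version: 1.2
ontology: ontosim-mixed

[Term]
id: GO:0100000
name: mf root
namespace: molecular_function

[Term]
id: GO:0100001
name: mf part
namespace: molecular_function
relationship: part_of GO:0100000

[Term]
id: GO:0100002
name: mf reg
namespace: molecular_function
is_a: GO:0100000
relationship: regulates GO:0100001

[Term]
id: GO:0100003
name: mf posreg
namespace: molecular_function
relationship: positively_regulates GO:0100002
is_a: GO:0100001

[Term]
id: GO:0200000
name: bp root
namespace: biological_process

[Term]
id: GO:0200001
name: bp child
namespace: biological_process
is_a: GO:0200000
relationship: part_of GO:0100000
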