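format-version: 1.2
data-version: fixtures/2020-01-01
ontology: ontosim-toy

[Term]
id: GO:0000001
name: R
namespace: molecular_function

[Term]
id: GO:0000002
name: C1
namespace: molecular_function
is_a: GO:0000001

[Term]
id: GO:0000003
name: C2
namespace: molecular_function
is_a: GO:0000001

[Term]
id: GO:0000004
name: A
namespace: molecular_function
alt_id: GO:0000104
is_a: GO:0000002

[Term]
id: GO:0000005
name: B
namespace: molecular_function
is_a: GO:0000002

[Term]
id: GO:0000006
name: D
namespace: molecular_function
is_a: GO:0000004
is_a: GO:0000005

[Term]
id: GO:0000099
name: gone
namespace: molecular_function
is_obsolete: true
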