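# Sentence templates for generated compound descriptions.
# Slots: {compound}, {parent}, {definition}, {framework}, {substituents}.
# A sentence is only rendered when all of its slots are available.
membership: "{compound} belongs to the class of compounds known as {parent}."
definition: "{definition}."
framework: "Structurally, it is an {framework}."
substituents: "It carries the following structural features: {substituents}."
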