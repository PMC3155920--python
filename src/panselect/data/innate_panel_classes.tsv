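group	n_genes
Receptors	19
Adaptors	10
Modulators	6
Acute Phase	20
Cellular Immunity	10
Antiinf. Cytokines	10
Neutrophil	9
Chemokines	14
Extracellular	6
Complement	8
Effector	15
Non classified	5
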