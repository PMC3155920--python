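gene	group	population	direction	unequivocal
TLR2	Receptors	AFR	positive	False
SOCS2	Modulators	AFR	positive	True
TOLLIP	Modulators	AFR	positive	False
IL17B	Neutrophil	AFR	positive	True
IL8	Chemokines	AFR	positive	True
MPO	Effector	AFR	positive	False
NGFR	Effector	AFR	positive	False
CTNNB1	Non classified	AFR	positive	False
LY96	Receptors	AFR	balancing	False
LTA	Acute Phase	AFR	balancing	False
IL18RAP	Acute Phase	AFR	balancing	False
IL1F5	Acute Phase	AFR	balancing	False
IL1F7	Acute Phase	AFR	balancing	False
CFH	Complement	AFR	balancing	False
C5	Complement	AFR	balancing	False
C3	Complement	AFR	balancing	False
NTRK1	Effector	AFR	balancing	False
LY64	Receptors	EUR	positive	True
TLR9	Receptors	EUR	positive	False
TLR10	Receptors	EUR	positive	True
IRAK4	Adaptors	EUR	positive	True
IL18BP	Acute Phase	EUR	positive	True
TGFB2	Antiinf. Cytokines	EUR	positive	False
CCR4	Chemokines	EUR	positive	False
ADAM33	Extracellular	EUR	positive	False
MPO	Effector	EUR	positive	False
TNFRSF18	Non classified	EUR	positive	False
CD14	Receptors	EUR	balancing	False
LY96	Receptors	EUR	balancing	False
TLR6	Receptors	EUR	balancing	False
IL1F5	Acute Phase	EUR	balancing	False
IL1A	Acute Phase	EUR	balancing	False
IL1F10	Acute Phase	EUR	balancing	False
IL18RAP	Acute Phase	EUR	balancing	False
IL1F7	Acute Phase	EUR	balancing	False
C3	Complement	EUR	balancing	False
ITGA8	Effector	EUR	balancing	False
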