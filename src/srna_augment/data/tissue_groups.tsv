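tissue	group
blood	blood_group
blood plasma	blood_group
blood serum	blood_group
peripheral blood	blood_group
umbilical cord blood	blood_group
serum	blood_group
buffy coat	blood_group
immortal human B cell	blood_group
liver	blood_group
lymphoblastoid cell	blood_group
brain	brain_group
cingulate gyrus	brain_group
motor cortex	brain_group
prefrontal cortex	brain_group
neocortex	brain_group
skin	epithelium_group
dermis	epithelium_group
epidermis	epithelium_group
breast	epithelium_group
oral mucosa	epithelium_group
larynx	epithelium_group
prostate gland	gland_group
testis	gland_group
kidney	gland_group
bladder	gland_group
uterine endometrium	gland_group
tonsil	gland_group
lymph node	gland_group
intestine	intestine_group
colon	intestine_group
ileal mucosa	intestine_group
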