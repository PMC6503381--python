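# Curated drug-like template molecules for the synthetic registry generator.
# Columns: NAME<TAB>CLASS<TAB>SMILES<TAB>ALT_SMILES(optional tautomer spelling)
# CLASS: organic | acid (salt-able COOH) | base (salt-able amine) |
#        stereo (contains stereocenters) | tautomer | organometallic | inorganic
aspirin	acid	CC(=O)Oc1ccccc1C(=O)O
benzoic-acid	acid	O=C(O)c1ccccc1
salicylic-acid	acid	O=C(O)c1ccccc1O
ibuprofen	acid	CC(C)Cc1ccc(C(C)C(=O)O)cc1
naproxen	acid	COc1ccc2cc(C(C)C(=O)O)ccc2c1
ketoprofen	acid	CC(C(=O)O)c1cccc(C(=O)c2ccccc2)c1
furosemide	acid	NS(=O)(=O)c1cc(C(=O)O)c(NCc2ccco2)cc1Cl
glycine	acid	NCC(=O)O
caffeine	organic	Cn1c(=O)c2c(ncn2C)n(C)c1=O
paracetamol	organic	CC(=O)Nc1ccc(O)cc1
nicotinamide	organic	NC(=O)c1cccnc1
theophylline	organic	Cn1c(=O)c2[nH]cnc2n(C)c1=O
sulfanilamide	organic	Nc1ccc(S(N)(=O)=O)cc1
metformin	base	CN(C)C(=N)NC(N)=N
lidocaine	base	CCN(CC)CC(=O)Nc1c(C)cccc1C
atenolol	base	CC(C)NCC(O)COc1ccc(CC(N)=O)cc1
propranolol	base	CC(C)NCC(O)COc1cccc2ccccc12
fluoxetine	base	CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1
dopamine	base	NCCc1ccc(O)c(O)c1
serotonin	base	NCCc1c[nH]c2ccc(O)cc12
trimethoprim	base	COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC
chloroquine	base	CCN(CC)CCCC(C)Nc1ccnc2cc(Cl)ccc12
alanine	stereo	C[C@H](N)C(=O)O
adrenaline	stereo	CNC[C@H](O)c1ccc(O)c(O)c1
nicotine	stereo	CN1CCC[C@H]1c1cccnc1
warfarin	stereo	CC(=O)C[C@@H](c1ccccc1)c1c(O)c2ccccc2oc1=O
lactic-acid	stereo	C[C@H](O)C(=O)O
menthol	stereo	CC(C)[C@@H]1CC[C@@H](C)C[C@H]1O
2-pyridone	tautomer	O=c1cccc[nH]1	Oc1ccccn1
4-pyridone	tautomer	O=c1cc[nH]cc1	Oc1ccncc1
uracil	tautomer	O=c1cc[nH]c(=O)[nH]1	Oc1ccnc(O)n1
2-mercaptopyridine	tautomer	S=c1cccc[nH]1	Sc1ccccn1
diazepam	organic	CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21
phenol	organic	Oc1ccccc1
aniline	organic	Nc1ccccc1
toluene	organic	Cc1ccccc1
imidazole	organic	c1c[nH]cn1
thiophene	organic	c1ccsc1
pyrazine	organic	c1cnccn1
benzamide	organic	NC(=O)c1ccccc1
phenylboronic-acid	organometallic	OB(O)c1ccccc1
tetraethylsilane	organometallic	CC[Si](CC)(CC)CC
trimethylarsine	organometallic	C[As](C)C
sodium-chloride	inorganic	[Na+].[Cl-]
potassium-bromide	inorganic	[K+].[Br-]
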