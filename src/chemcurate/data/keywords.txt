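# Name-triage keywords: category<TAB>keyword<TAB>word_boundary(0/1)
# remove  : substance has no single defined structure -> rejected
# manual  : ambiguous wording -> record needs a manual check
# isomer  : isomeric-mixture wording -> kept (stereochemistry is stripped)
remove	mixture	0
remove	reaction mass	0
remove	reaction product	0
remove	uvcb	0
remove	polymer	0
manual	metabolite	0
manual	formulation	0
manual	degradate	0
manual	product	1
manual	products	1
manual	derivative	0
isomer	isomer	1
isomer	isomers	1
isomer	isomeric	0
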