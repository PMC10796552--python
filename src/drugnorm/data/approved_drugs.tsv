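name	is_target	class
belbuca	true	buprenorphine
buprenex	true	buprenorphine
buprenorphine	true	buprenorphine
butrans	true	buprenorphine
buprenorphine/naloxone	true	buprenorphine
suboxone	true	buprenorphine
codeine	true	codeine
acetaminophen/codeine	true	codeine
capital and codeine	true	codeine
acetaminophen 300 mg/codeine phosphate 30 mg oral tablet [tylenol with codeine]	true	codeine
tylenol with codeine	true	codeine
acetaminophen/butalbital/caffeine/codeine	true	codeine
fioricet with codeine	true	codeine
aspirin/butalbital/caffeine/codeine	true	codeine
fiorinal with codeine	true	codeine
aspirin/carisoprodol/codeine	true	codeine
codeine/promethazine	true	codeine
dihydrocodeine	true	dihydrocodeine
acetaminophen/caffeine/dihydrocodeine	true	dihydrocodeine
trezix	true	dihydrocodeine
abstral	true	fentanyl
actiq	true	fentanyl
duragesic	true	fentanyl
fentanyl	true	fentanyl
fentora	true	fentanyl
lazanda	true	fentanyl
subsys	true	fentanyl
droperidol/fentanyl	true	fentanyl
hydrocodone	true	hydrocodone
zohydro	true	hydrocodone
acetaminophen/hydrocodone	true	hydrocodone
lortab	true	hydrocodone
lorcet	true	hydrocodone
norco	true	hydrocodone
vicodin	true	hydrocodone
homatropine/hydrocodone	true	hydrocodone
hycodan	true	hydrocodone
tussigon	true	hydrocodone
chlorpheniramine/hydrocodone	true	hydrocodone
tussicaps	true	hydrocodone
hydrocodone/ibuprofen	true	hydrocodone
vicoprofen	true	hydrocodone
hydrocodone/pseudoephedrine	true	hydrocodone
dilaudid	true	hydromorphone
exalgo	true	hydromorphone
hydromorphone	true	hydromorphone
meperidine	true	meperidine
dolophine	true	methadone
methadone hydrochloride	true	methadone
methadose	true	methadone
kadian	true	morphine
morphine sulfate	true	morphine
ms contin	true	morphine
embeda	true	morphine
oxycodone	true	oxycodone
oxycontin	true	oxycodone
acetaminophen/oxycodone	true	oxycodone
percocet	true	oxycodone
aspirin/oxycodone	true	oxycodone
opana	true	oxymorphone
oxymorphone hydrochloride	true	oxymorphone
nucynta	true	tapentadol
tapentadol	true	tapentadol
conzip	true	tramadol
tramadol hydrochloride	true	tramadol
ultram	true	tramadol
ultracet	true	tramadol
aspirin	false	
ibuprofen	false	
acetaminophen	false	
naloxone	false	
metformin hydrochloride	false	
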