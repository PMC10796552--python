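# Opioid concept lexicon: concept_id|term|term_type[|class]
# Curated FDA-approved prescription-opioid concepts with observed FAERS name variants.
1716058|belbuca|preferred|buprenorphine
203840|buprenex|preferred|buprenorphine
1819|buprenorphine|preferred|buprenorphine
904871|butrans|preferred|buprenorphine
352364|buprenorphine/naloxone|preferred|buprenorphine
352990|suboxone|preferred|buprenorphine
2670|codeine|preferred|codeine
817579|acetaminophen/codeine|preferred|codeine
993764|capital and codeine|preferred|codeine
993837|acetaminophen 300 mg/codeine phosphate 30 mg oral tablet [tylenol with codeine]|preferred|codeine
220586|tylenol with codeine|preferred|codeine
689561|acetaminophen/butalbital/caffeine/codeine|preferred|codeine
217126|fioricet with codeine|preferred|codeine
214160|aspirin/butalbital/caffeine/codeine|preferred|codeine
217127|fiorinal with codeine|preferred|codeine
689522|aspirin/carisoprodol/codeine|preferred|codeine
214444|codeine/promethazine|preferred|codeine
23088|dihydrocodeine|preferred|dihydrocodeine
689569|acetaminophen/caffeine/dihydrocodeine|preferred|dihydrocodeine
746611|trezix|preferred|dihydrocodeine
1053648|abstral|preferred|fentanyl
215008|actiq|preferred|fentanyl
151678|duragesic|preferred|fentanyl
4337|fentanyl|preferred|fentanyl
668619|fentora|preferred|fentanyl
1115547|lazanda|preferred|fentanyl
1237051|subsys|preferred|fentanyl
49991|droperidol/fentanyl|preferred|fentanyl
5489|hydrocodone|preferred|hydrocodone
1442523|zohydro|preferred|hydrocodone
214182|acetaminophen/hydrocodone|preferred|hydrocodone
144254|lortab|preferred|hydrocodone
491666|lorcet|preferred|hydrocodone
218772|norco|preferred|hydrocodone
128793|vicodin|preferred|hydrocodone
214614|homatropine/hydrocodone|preferred|hydrocodone
992657|hycodan|preferred|hydrocodone
220542|tussigon|preferred|hydrocodone
214392|chlorpheniramine/hydrocodone|preferred|hydrocodone
730984|tussicaps|preferred|hydrocodone
214627|hydrocodone/ibuprofen|preferred|hydrocodone
220826|vicoprofen|preferred|hydrocodone
214631|hydrocodone/pseudoephedrine|preferred|hydrocodone
224913|dilaudid|preferred|hydromorphone
902730|exalgo|preferred|hydromorphone
3423|hydromorphone|preferred|hydromorphone
6754|meperidine|preferred|meperidine
202370|dolophine|preferred|methadone
218337|methadone hydrochloride|preferred|methadone
218337|methadone hcl|variant
218337|methadone hydrochloride.|variant
218337|methadone ap hp|variant
218337|methadone/methadone hydrochloride|variant
218337|methadone ap?hp|variant
218337|methadone (chlorhydrate de)|variant
218337|methadone chlorhydrate ap hp|variant
218337|ketalgin (methadone)|variant
218337|methadone [methadone hydrochloride]|variant
218337|methadon alternova|variant
218337|methadon hcl|variant
218337|methadone chlorhydrate|variant
218337|methadone intensol|variant
152751|methadose|preferred|methadone
203240|kadian|preferred|morphine
30236|morphine sulfate|preferred|morphine
203354|ms contin|preferred|morphine
859959|embeda|preferred|morphine
7804|oxycodone|preferred|oxycodone
218986|oxycontin|preferred|oxycodone
214183|acetaminophen/oxycodone|preferred|oxycodone
42844|percocet|preferred|oxycodone
214256|aspirin/oxycodone|preferred|oxycodone
214256|oxycodone and aspirin|variant
214256|oxycodone/aspirin|variant
214256|aspirin w/oxycodone|variant
214256|oxycodone and aspirin/00554201/|variant
214256|oxycodone/asa|variant
214256|oxycodone with aspirin|variant
214256|oxycodone-aspirin|variant
214256|oxycodone-asa|variant
214256|oxycod/asa|variant
214256|aspirin + oxycodone|variant
214256|oxycodone and asa|variant
643147|opana|preferred|oxymorphone
82064|oxymorphone hydrochloride|preferred|oxymorphone
854137|nucynta|preferred|tapentadol
787390|tapentadol|preferred|tapentadol
1148479|conzip|preferred|tramadol
82110|tramadol hydrochloride|preferred|tramadol
220606|ultram|preferred|tramadol
353062|ultracet|preferred|tramadol
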