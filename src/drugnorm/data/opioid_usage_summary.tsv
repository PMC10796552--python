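class	concept_id	preferred_name	n_variants	freq_preferred	freq_all	pct_preferred
buprenorphine	1716058	belbuca	6	553	577	95.8
buprenorphine	203840	buprenex	5	57	98	58.2
buprenorphine	1819	buprenorphine	28	2032	10383	19.6
buprenorphine	904871	butrans	13	52880	52992	99.8
buprenorphine	352364	buprenorphine/naloxone	52	33	2626	1.3
buprenorphine	352990	suboxone	9	19420	21450	90.5
codeine	2670	codeine	45	24572	25926	94.8
codeine	817579	acetaminophen/codeine	252	4	28225	0.0
codeine	993764	capital and codeine	2	12	17	70.6
codeine	993837	acetaminophen 300 mg/codeine phosphate 30 mg oral tablet [tylenol with codeine]	18	0	3544	0.0
codeine	220586	tylenol with codeine	18	7948	9708	81.9
codeine	689561	acetaminophen/butalbital/caffeine/codeine	6	0	73	0.0
codeine	217126	fioricet with codeine	4	271	408	66.4
codeine	214160	aspirin/butalbital/caffeine/codeine	5	0	19	0.0
codeine	217127	fiorinal with codeine	7	156	321	48.6
codeine	689522	aspirin/carisoprodol/codeine	2	0	107	0.0
codeine	214444	codeine/promethazine	20	0	412	0.0
dihydrocodeine	23088	dihydrocodeine	24	2515	4183	60.1
dihydrocodeine	689569	acetaminophen/caffeine/dihydrocodeine	10	0	88	0.0
dihydrocodeine	746611	trezix	2	28	52	53.8
fentanyl	1053648	abstral	11	959	1115	86.0
fentanyl	215008	actiq	2	26948	26952	100.0
fentanyl	151678	duragesic	35	36144	42325	85.4
fentanyl	4337	fentanyl	52	26441	77019	34.3
fentanyl	668619	fentora	10	26069	27515	94.7
fentanyl	1115547	lazanda	5	199	219	90.9
fentanyl	1237051	subsys	4	9191	9372	98.1
fentanyl	49991	droperidol/fentanyl	5	0	64	0.0
hydrocodone	5489	hydrocodone	30	48914	51638	94.7
hydrocodone	1442523	zohydro	3	444	450	98.7
hydrocodone	214182	acetaminophen/hydrocodone	286	73	77739	0.1
hydrocodone	144254	lortab	31	21941	23044	95.2
hydrocodone	491666	lorcet	13	524	1042	50.3
hydrocodone	218772	norco	22	57621	57839	99.6
hydrocodone	128793	vicodin	47	41950	42663	98.3
hydrocodone	214614	homatropine/hydrocodone	26	0	479	0.0
hydrocodone	992657	hycodan	12	392	569	68.9
hydrocodone	220542	tussigon	3	14	25	56.0
hydrocodone	214392	chlorpheniramine/hydrocodone	22	0	333	0.0
hydrocodone	730984	tussicaps	3	44	53	83.0
hydrocodone	214627	hydrocodone/ibuprofen	28	131	867	15.1
hydrocodone	220826	vicoprofen	4	1226	1239	99.0
hydrocodone	214631	hydrocodone/pseudoephedrine	2	0	15	0.0
hydromorphone	224913	dilaudid	30	50623	51177	98.9
hydromorphone	902730	exalgo	6	9647	9963	96.8
hydromorphone	3423	hydromorphone	70	42380	48255	87.8
meperidine	6754	meperidine	38	901	2530	35.6
methadone	202370	dolophine	6	476	619	76.9
methadone	218337	methadone hydrochloride	14	1261	14717	8.6
methadone	152751	methadose	3	3079	3103	99.2
morphine	203240	kadian	9	21926	22161	98.9
morphine	30236	morphine sulfate	58	15814	45455	34.8
morphine	203354	ms contin	29	36726	37588	97.7
morphine	859959	embeda	3	1325	1609	82.3
oxycodone	7804	oxycodone	87	72895	123099	59.2
oxycodone	218986	oxycontin	48	92489	99146	93.3
oxycodone	214183	acetaminophen/oxycodone	144	19	21595	0.1
oxycodone	42844	percocet	41	71517	76726	93.2
oxycodone	214256	aspirin/oxycodone	12	0	110	0.0
oxymorphone	643147	opana	11	28670	28768	99.7
oxymorphone	82064	oxymorphone hydrochloride	2	217	18454	1.2
tapentadol	854137	nucynta	3	28254	28332	99.7
tapentadol	787390	tapentadol	7	1341	1528	87.8
tramadol	1148479	conzip	3	51	113	45.1
tramadol	82110	tramadol hydrochloride	220	4994	128410	3.9
tramadol	220606	ultram	21	17853	18120	98.5
tramadol	353062	ultracet	19	4933	5220	94.5
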