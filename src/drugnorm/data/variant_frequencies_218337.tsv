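raw_name	count
methadone hcl	11040
methadone hydrochloride.	2117
methadone hydrochloride	1261
methadone ap hp	215
methadone/methadone hydrochloride	17
methadone ap?hp	12
methadone (chlorhydrate de)	11
methadone chlorhydrate ap hp	9
ketalgin (methadone)	8
methadone [methadone hydrochloride]	8
methadon alternova	6
methadon hcl	6
methadone chlorhydrate	4
methadone intensol	3
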