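raw_name	count
oxycodone and aspirin	55
oxycodone/aspirin	10
aspirin w/oxycodone	9
oxycodone and aspirin/00554201/	5
oxycodone/asa	5
aspirin/oxycodone	4
oxycodone with aspirin	4
oxycodone-aspirin	4
oxycodone-asa	4
oxycod/asa	4
aspirin + oxycodone	3
oxycodone and asa	3
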