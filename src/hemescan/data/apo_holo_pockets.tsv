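# CASTp-style pocket measurements for the ten curated apo-holo heme
# protein pairs (published survey values, consumed as external input).
# Pairs whose pocket could not be measured carry empty volume/area.
# pair_id: holo chain label; role: holo|apo.
pair_id	chain	role	volume_A3	area_A2	identity_pct	rmsd_A
1KBIA	1KBIA	holo	458.1	432	99	0.40
1KBIA	1SZFB	apo	1039.3	708.3	99	0.40
1N45A	1N45A	holo	1634.7	1139.3	100	0.86
1N45A	1S8CD	apo	845.1	634.4	100	0.86
1N5UA	1N5UA	holo			100	0.60
1N5UA	3CX9A	apo			100	0.60
2ITFA	2ITFA	holo	721.7	521	100	0.60
2ITFA	2ITEB	apo	803.4	551	100	0.60
2NWBA	2NWBA	holo			96	0.75
2NWBA	1ZEEB	apo			96	0.75
2OFRX	2OFRX	holo	1211.1	857.4	100	1.03
2OFRX	2OFMX	apo	783.3	642.7	100	1.03
2R7AA	2R7AA	holo	1362.6	963.4	100	0.91
2R7AA	2RG7D	apo	1558.1	1019.6	100	0.91
2ZDOA	2ZDOA	holo	808.7	553.9	99	0.59
2ZDOA	1XBWD	apo	766.9	544.2	99	0.59
3CQVA	3CQVA	holo	1638.3	1099	94	2.32
3CQVA	2V7CA	apo	537.1	436.2	94	2.32
3EMMA	3EMMA	holo	399	383.1	100	0.53
3EMMA	2A13A	apo	910.8	635.2	100	0.53
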