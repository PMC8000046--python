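# Illustrative substrate-association map bundled with cazhotspot.
# Canonical plant-cell-wall enzyme activities and their usual target
# substrate(s); assembled for testing and demonstration, NOT a curated
# production map. Supply your own map with --substrate-map for analyses.
# Columns: ec_pattern, family_pattern ("*" = any), substrates (comma-separated).
ec_pattern	family_pattern	substrates
3.2.1.4	*	cellulose
3.2.1.91	*	cellulose
3.2.1.176	*	cellulose
3.2.1.21	*	cellulose
3.2.1.74	*	cellulose
3.2.1.151	*	cellulose
3.2.1.8	*	xylan
3.2.1.37	*	xylan
3.2.1.55	*	xylan
3.2.1.131	*	xylan
3.2.1.139	*	xylan
3.2.1.32	*	xylan
3.1.1.72	*	xylan
3.1.1.73	*	xylan,pectin
3.2.1.15	*	pectin
3.2.1.67	*	pectin
3.2.1.82	*	pectin
3.1.1.11	*	pectin
3.2.1.89	*	pectin
3.2.1.99	*	pectin
4.2.2.2	*	pectin
4.2.2.10	*	pectin
4.2.2.23	*	pectin
1.10.3.2	*	lignin
1.11.1.13	*	lignin
1.11.1.14	*	lignin
1.11.1.16	*	lignin
1.1.3.7	*	lignin
*	GH28	pectin
*	GH11	xylan
*	PL1	pectin
*	PL3	pectin
*	PL4	pectin
*	CE8	pectin
*	AA1	lignin
*	AA2	lignin
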