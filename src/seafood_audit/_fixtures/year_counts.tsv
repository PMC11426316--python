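cohort	year	n	semantic	invalid_name	product_substitution	pct_total	pct_conservative
invertebrate	2016	1	0	0	1	100.0	100.0
invertebrate	2017	1	0	0	1	100.0	100.0
invertebrate	2018	47	4	0	14	38.3	29.8
invertebrate	2019	16	3	0	3	37.5	18.8
invertebrate	2020	44	8	0	3	25.0	6.8
finfish	2014	19	0	0	6	31.6	31.6
finfish	2016	57	5	0	12	29.8	21.1
finfish	2017	132	19	6	28	40.2	25.8
finfish	2018	62	10	0	10	32.2	16.1
finfish	2019	60	4	2	7	21.7	15.0
finfish	2020	17	0	0	3	17.6	17.6
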