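patient	n_ieds	hr_detected	side	shape	onset_s	peak_s	end_s	duration_s
PA01	7	1	affected	HbO initial dip then HbO up	0	20	35	35
PA01	7	1	unaffected	initial dip then HbO up	0	17.5	35	35
PA02	209	1	affected	HbO up then HbO down	0	3.8	11	15
PA02	209	1	unaffected	HbO up, lower amplitude	0	2.5	5	5
PA03	32	1	affected	small HbO up then HbO down	7	17	20	20
PA03	32	1	unaffected	small HbO up then HbO down	7	17	20	20
PA04	15	1	affected	HbO up then HbO down	5.5	8.5	14	8.5
PA04	15	1	unaffected	HbO down	0	2	4	4
PA05	900	0	affected
PA05	900	0	unaffected
PA06	22	1	affected	HbO up then HbO decrease	0	4.5	30	30
PA06	22	1	unaffected	HbO up then HbO decrease	0	6	35	35
PA07	58	1	affected	HbO up then HbO decrease	-5	3.5	17.3	22.3
PA07	58	1	unaffected	HbO up, weaker	-4.5	3.5	17.5	22
PA08	10	1	affected	HbO down then HbO up	-4	5	10.7	14.7
PA08	10	1	unaffected	HbO down then HbO up	-3.6	7.5	11.5	15
PA09	475	1	affected	HbO up	-9.5	5	20.5	30
PA09	475	1	unaffected	HbO up	-19	0	15	34
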