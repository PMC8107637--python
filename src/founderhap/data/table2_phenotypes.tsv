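individual	family	sex	age_of_initial_presentation	age_of_examination	optic_atrophy	retinal_dystrophy	macula_edema	retinal_vessels_attenuation	cataract	nystagmus	squint	latest_bcva	constricted_visual_field	nyctalopia	hearing_impairment	ataxia_balance_problems	sensory_neuropathy	motor_neuropathy	dizziness	tremor
family_1-II:1	family_1	M	3 y	11 y	Yes (3)	No	No	No	No	Yes (3)	Yes (3)	HM	No	No	No	Yes (11)	No	No	Yes (11)	Yes (12)
family_2-II:2	family_2	M	4 y	11 y	Yes (11)	Yes (4)	Yes (5)	Yes (11)	Yes (11)	No	No	LP	Yes	Yes	Yes (11)	Yes (late teens)	Yes (late teens)	Yes (late teens)	No	No
family_2-II:1	family_2	M	14 y	14 y	Yes (14)	Yes (14)	No	Yes (14)	No	No	No	0.06 and 0.1	Yes	No	Yes (late teens)	Yes (late teens)	Yes (late teens)	Yes (late teens)	No	No
family_3-II:1	family_3	M	7 y	26 y	Yes (7)	Yes (7)	No	Yes (8)	Yes (18)	Yes (14)	Yes (16)	HM and LP	Yes	Yes	Yes (20)	No	No	No	Yes (late teens)	Yes (15)
family_4-II:1	family_4	M	22 y	25 y	Yes (25)	No	No	No	No	No	No	CF and 6/36	No	No	No	No	Yes (22)	Yes (22)	No	No
family_5-II:4	family_5	F	40s	45 y	Yes (40s)	No	No	No	No	No	No	6/36 and 6/24	No	No	Yes (40s)	Yes (40s)	Yes (40s)	Yes (40s)	No	No
family_6-II:1	family_6	M	Childhood	7 y	Yes (>7)	Yes (7)	No	No	Yes (17 to 18)	Yes (>7)	No	ND	ND	ND	No	Yes (childhood)	Yes (childhood)	No	No	No
family_7-II:2	family_7	M	2.5 years	26 y	Yes (7)	Yes (7)	Yes (17)	Yes (ND)	No	No	No	6/12 and 6/18	Yes	ND	No	Yes (2.5)	No	No	No	No
family_7-II:1	family_7	F	3.5 y	10	Yes (3.5)	Yes (3.5)	No	No	No	No	No	6/36	Yes	ND	No	Yes (15)	No	No	No	No
family_8-II:1	family_8	F	42 y	42 y	Yes (42)	Possible	No	No	No	No	No	ND	ND	ND	Yes (42)	Yes (42)	Yes (42)	Yes (42)	No	No
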