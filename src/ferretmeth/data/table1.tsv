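sample_id	studbook_no	name	tissue	collection_date	age_at_sampling	avg_litter_size	testes_status	sperm_count_per_ml
B2_2	7611	Gale	Blood	11_29_2017	4	0	Not_Firm	n/a
B3_1	7419	Tanis	Blood	04_11_2018	6	2	Firm	n/a
B4_1	8519	Jensen	Blood	12_12_2017	2	0	Not_Firm	n/a
B5_2	8520	Padalecki	Blood	04_10_2018	3	2	Firm	n/a
B6_2	7685	Cane	Blood	08_08_2018	5	4.5	Not_Firm	n/a
B7_2	7916	Eamon	Blood	12_04_2017	4	3.8	Not_Firm	n/a
B8_1	8161	Flagstaff	Blood	12_05_2017	3	4.3	Not_Firm	n/a
B9_1	8393	Pancake	Blood	05_09_2018	3	0	Firm	n/a
S1_1	6536	Capone	Sperm	03_27_2012	3	1.5	Firm	407.1
S2_2	7611	Gale	Sperm	04_25_2017	4	0	Firm	1018.4
S3_2	7419	Tanis	Sperm	04_11_2018	6	2	Firm	572.1
S4_1	8519	Jensen	Sperm*	04_5_2019	4	0	Firm	69.8
S5_1	8520	Padalecki	Sperm	04_10_2018	3	2	Firm	888.2
T1_2	6536	Capone	Testes	05_27_2015	6	1.5	Firm	n/a
T2_1	7611	Gale	Testes*	02_13_2018	5	0	Firm	n/a
T3_2	7419	Tanis	Testes	04_11_2018	6	2	Firm	n/a
T4_1	8519	Jensen	Testes	08_01_2019	4	0	Not_Firm	n/a
T5_1	8520	Padalecki	Testes	10_25_2018	3	2	Not_Firm	n/a
T6_1	7685	Cane	Testes	08_10_2018	5	4.5	Not_Firm	n/a
T7_1	7916	Eamon	Testes	05_02_2018	5	3.8	Firm	n/a
T8_2	8161	Flagstaff	Testes	01_16_2020	6	4.3	Firm	n/a
T9_2	8393	Pancake	Testes	05_10_2018	3	0	Firm	n/a
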