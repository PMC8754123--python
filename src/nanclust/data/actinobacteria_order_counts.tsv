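class	order	n_strains	n_sac_strains	n_type	n_sac_type
Acidimicrobiia	Acidimicrobiales	3	0	3	0
Acidimicrobiia	Iamiales	4	0	4	0
Actinomycetia	Acidothermales	1	0	1	0
Actinomycetia	Actinocatenisporales	1	0	1	0
Actinomycetia	Actinomycetales	229	179	65	45
Actinomycetia	Antricoccales	4	0	3	0
Actinomycetia	Beutenbergiales	7	1	5	1
Actinomycetia	Bifidobacteriales	748	187	91	24
Actinomycetia	Bogoriellales	13	1	8	1
Actinomycetia	Brevibacteriales	70	33	13	4
Actinomycetia	Catenulisporales	2	0	2	0
Actinomycetia	Cellulomonadales	133	17	61	5
Actinomycetia	Cryptosporangiales	3	0	3	0
Actinomycetia	Demequinales	28	0	17	0
Actinomycetia	Dermabacterales	34	21	12	8
Actinomycetia	Dermatophilales	114	12	60	8
Actinomycetia	Frankiales	30	0	11	0
Actinomycetia	Geodermatophilales	72	0	34	0
Actinomycetia	Glycomycetales	16	0	14	0
Actinomycetia	Jatrophihabitantales	4	0	1	0
Actinomycetia	Jiangellales	17	0	13	0
Actinomycetia	Kineosporiales	13	0	6	0
Actinomycetia	Microbacteriales	792	53	173	12
Actinomycetia	Micrococcales	499	121	81	19
Actinomycetia	Micromonosporales	270	33	103	10
Actinomycetia	Motilibacterales	2	0	2	0
Actinomycetia	Mycobacteriales	1759	237	429	40
Actinomycetia	Nakamurellales	7	1	6	1
Actinomycetia	Propionibacteriales	309	20	129	14
Actinomycetia	Pseudonocardiales	247	9	169	3
Actinomycetia	Ruaniales	8	3	2	1
Actinomycetia	Sporichthyales	1	0	1	0
Actinomycetia	Streptomycetales	1286	184	265	25
Actinomycetia	Streptosporangiales	195	19	118	13
Coriobacteriia	Coriobacteriales	154	116	19	10
Coriobacteriia	Eggerthellales	81	48	26	13
Nitriliruptoria	Egibacterales	1	0	1	0
Nitriliruptoria	Egicoccales	1	0	1	0
Nitriliruptoria	Euzebyales	2	0	2	0
Nitriliruptoria	Nitriliruptorales	1	0	1	0
Rubrobacteria	Gaiellales	1	0	1	0
Rubrobacteria	Rubrobacterales	5	0	3	0
Thermoleophilia	Solirubrobacterales	12	0	8	0
Thermoleophilia	Thermoleophilales	1	0	1	0
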