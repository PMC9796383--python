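drug_name	indications	citations	studies	models
Riluzole	Amyotrophic lateral sclerosis	482	4	4
Memantine	Alzheimer disease	322	19	5
Verapamil	Angina;hypertension;cluster headache	165	12	6
Meperidine	Pain	155	3	2
Amlodipine	Hypertension;angina	152	4	3
Dextromethorphan	Cough	145	22	6
Nifedipine	Angina;hypertension;Raynaud phenomenon;premature labor	86	22	6
Fluoxetine	Depression;bulimia nervosa;obsessive-compulsive disorder	54	11	3
Scopolamine	Motion sickness;excessive respiratory secretions	54	8	3
Aripiprazole	Schizophrenia	52	3	3
Bromocriptine	Parkinson disease;endocrine disorders	52	3	2
Pimozide	Schizophrenia	51	3	4
Apomorphine	Parkinson disease	42	10	4
Bumetanide	Edema	28	5	4
Celecoxib	Osteoarthritis;rheumatoid arthritis;ankylosing spondylitis	25	4	2
Dexamethasone	Inflammatory and allergic disorders;congenital adrenal hyperplasia;cerebral edema	25	3	3
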