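# ICD-10 (2010) chapter blocks: start, end (inclusive), label, profile_eligible
# Codes falling in a gap between blocks (e.g. D49, E95) are assigned to the
# preceding chapter. Z00-Z99 is excluded from disease-profile tables.
A00	B99	Certain infectious and parasitic diseases	1
C00	D48	Neoplasms	1
D50	D89	Diseases of the blood and blood-forming organs	1
E00	E90	Endocrine, nutritional and metabolic diseases	1
F00	F99	Mental and behavioural disorders	1
G00	G99	Diseases of the nervous system	1
H00	H59	Diseases of the eye and adnexa	1
H60	H95	Diseases of the ear and mastoid process	1
I00	I99	Diseases of the circulatory system	1
J00	J99	Diseases of the respiratory system	1
K00	K93	Diseases of the digestive system	1
L00	L99	Diseases of the skin and subcutaneous tissue	1
M00	M99	Diseases of the musculoskeletal system and connective tissue	1
N00	N99	Diseases of the genitourinary system	1
O00	O99	Pregnancy, childbirth and the puerperium	1
P00	P96	Certain conditions originating in the perinatal period	1
Q00	Q99	Congenital malformations, deformations and chromosomal abnormalities	1
R00	R99	Symptoms, signs and abnormal clinical and laboratory findings	1
S00	T98	Injury, poisoning and certain other consequences of external causes	1
U00	U99	Codes for special purposes	1
V01	Y98	External causes of morbidity and mortality	1
Z00	Z99	Factors influencing health status and contact with health services	0
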