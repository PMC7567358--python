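condition,atc_pattern,min_rx_per_year,exception_codes,flag,provenance
Cardiovascular and cerebrovascular disease,C01,2,,,unverified
Cardiovascular and cerebrovascular disease,C02,2,,,unverified
Cardiovascular and cerebrovascular disease,C03,2,,,unverified
Cardiovascular and cerebrovascular disease,C07,2,,,unverified
Cardiovascular and cerebrovascular disease,C08,2,,,unverified
Cardiovascular and cerebrovascular disease,C09,2,,,unverified
Cardiovascular and cerebrovascular disease,B01,2,,,unverified
Respiratory illness,R03,2,,,unverified
Exocrine pancreas failure,A09A,1,,,unverified
Cystic fibrosis,R05CB13,1,,,unverified
Tuberculosis,J04A,1,,,unverified
Cancer,L01,1,,,unverified
Cancer,L02,1,,,unverified
Acid related disorders/peptic ulcer,A02B,3,,,unverified
Irritable colon,A03AA,2,,,unverified
Liver diseases,A05,2,,,unverified
Chronic hepatitis,J05AP,1,,,unverified
Diabetes,A10,2,,,unverified
Glaucoma,S01E,2,,,unverified
Chronic renal disease,B03XA,1,,,unverified
Chronic renal disease,V03AE,1,,,unverified
Anaemias,B03A,2,,,unverified
Anaemias,B03B,2,,,unverified
Bone diseases,M05B,2,,,unverified
Inflammatory bowel + rheumatologic disease,A07EC,2,,,unverified
Inflammatory bowel + rheumatologic disease,L04AB,1,,,unverified
Pain and inflammation,M01A,3,,,unverified
Pain and inflammation,N02A,3,,,unverified
Hyperuricemia/gout,M04A,2,,,unverified
Dermatological severe,D05,2,,,unverified
Transplantation,L04AA,1,L04AA23;L04AA27;L04AA31,,unverified
Hyperlipidaemia,C10,2,,,unverified
HIV,J05AR,1,,,unverified
HIV,J05AG,1,,,unverified
HIV,J05AE,1,,,unverified
Hypothyroidism,H03A,2,,,unverified
Epilepsy,N03A,2,,,unverified
Epilepsy,N05CD08,2,,,unverified
Dementia,N06D,1,,,unverified
Parkinson's disease,N04,2,,,unverified
"Depression, anxiety, OCD",N06A,2,,,unverified
"Depression, anxiety, OCD",N05BA,2,,,unverified
"Depression, anxiety, OCD",N05CD,2,N05CD08,,unverified
Bipolar disorders,N05AN01,1,,,unverified
Psychosis,N05A,2,N05AN01,,unverified
Multiple sclerosis,L03AB07,1,,,unverified
Multiple sclerosis,L03AB08,1,,,unverified
Multiple sclerosis,L04AA23,1,,,unverified
Multiple sclerosis,L04AA27,1,,,unverified
Multiple sclerosis,L04AA31,1,,,unverified
Haemorrhagic diathesis,B02B,1,,,unverified
Allergic disorders,R06A,3,,,unverified
Addictive disorders,N07BB,1,,,unverified
Addictive disorders,N07BC,1,,,unverified
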