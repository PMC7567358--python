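condition,coefficient,weight
Cancer,1.039,10
Chronic renal disease,0.689,7
Psychosis,0.677,7
Haemorrhagic diathesis,0.446,4
"Depression, anxiety, OCD",0.440,4
Epilepsy,0.422,4
Anaemias,0.422,4
Parkinson's disease,0.325,3
Diabetes,0.293,3
Hyperuricemia/gout,0.286,3
Irritable colon,0.282,3
Transplantation,0.256,3
Dementia,0.244,2
Cardiovascular and cerebrovascular disease,0.177,2
Acid related disorders/peptic ulcer,0.139,1
Respiratory illness,0.108,1
Exocrine pancreas failure,0.087,1
Liver diseases,0.082,1
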