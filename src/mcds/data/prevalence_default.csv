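condition,prevalence
Cardiovascular and cerebrovascular disease,0.571
Respiratory illness,0.131
Exocrine pancreas failure,0.003
Cystic fibrosis,0.000003
Tuberculosis,0.001
Cancer,0.036
Acid related disorders/peptic ulcer,0.248
Irritable colon,0.004
Liver diseases,0.022
Chronic hepatitis,0.002
Diabetes,0.098
Glaucoma,0.067
Chronic renal disease,0.001
Anaemias,0.039
Bone diseases,0.069
Inflammatory bowel + rheumatologic disease,0.008
Pain and inflammation,0.212
Hyperuricemia/gout,0.067
Dermatological severe,0.019
Transplantation,0.001
Hyperlipidaemia,0.250
HIV,0.002
Hypothyroidism,0.093
Epilepsy,0.013
Dementia,0.008
Parkinson's disease,0.013
"Depression, anxiety, OCD",0.148
Bipolar disorders,0.002
Psychosis,0.024
Multiple sclerosis,0.0004
Haemorrhagic diathesis,0.004
Allergic disorders,0.036
Addictive disorders,0.000003
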