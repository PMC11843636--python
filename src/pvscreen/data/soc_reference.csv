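soc,a,b,c,d,ror,ci_low,ci_high,prr,chi2,flag
General disorders and administration site conditions,338,1185,971,4217,1.24,1.08,1.42,1.19,9.06,ror_only
Nervous system disorders,228,1295,356,4832,2.39,2,2.85,2.18,97.43,both
Investigations,195,1328,603,4585,1.12,0.94,1.33,1.1,1.57,none
Gastrointestinal disorders,188,1335,481,4707,1.38,1.15,1.65,1.33,12.39,ror_only
Musculoskeletal and connective tissue disorders,99,1424,326,4862,1.04,0.82,1.31,1.03,0.09,none
"Injury, poisoning and procedural complications",77,1446,494,4694,0.51,0.4,0.65,0.53,30.17,none
"Respiratory, thoracic and mediastinal disorders",62,1461,149,5039,1.44,1.06,1.94,1.42,5.56,ror_only
Renal and urinary disorders,59,1464,252,4936,0.79,0.59,1.05,0.8,2.58,none
Vascular disorders,52,1471,204,4984,0.86,0.63,1.18,0.87,0.86,none
Infections and infestations,51,1472,266,4922,0.64,0.47,0.87,0.65,8.28,none
Skin and subcutaneous tissue disorders,48,1475,271,4917,0.59,0.43,0.81,0.6,11.16,none
Psychiatric disorders,32,1491,233,4955,0.46,0.31,0.66,0.47,17.73,none
Metabolism and nutrition disorders,27,1496,133,5055,0.69,0.45,1.04,0.69,3.16,none
Cardiac disorders,13,1510,39,5149,1.14,0.61,2.13,1.14,0.16,none
Eye disorders,12,1511,82,5106,0.49,0.27,0.91,0.5,5.36,none
Blood and lymphatic system disorders,10,1513,24,5164,1.42,0.68,2.98,1.42,0.88,none
Ear and labyrinth disorders,9,1514,7,5181,4.4,1.64,11.83,4.38,10.29,both
Immune system disorders,7,1516,37,5151,0.64,0.29,1.44,0.64,1.16,none
Hepatobiliary disorders,5,1518,30,5158,0.57,0.22,1.46,0.57,1.42,none
Surgical and medical procedures,4,1519,103,5085,0.13,0.05,0.35,0.13,22.27,none
Reproductive system and breast disorders,4,1519,49,5139,0.28,0.1,0.77,0.28,6.99,none
Endocrine disorders,1,1522,48,5140,0.07,0.01,0.51,0.07,12,none
Social circumstances,1,1522,5,5183,0.68,0.08,5.83,0.68,0.12,none
Product issues,1,1522,4,5184,0.85,0.1,7.62,0.85,0.02,none
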