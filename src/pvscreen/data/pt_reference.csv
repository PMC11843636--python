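soc,pt,a,b,c,d,ror,ci_low,ci_high,prr,chi2,source
Blood and lymphatic system disorders,Anaemia,9,1514,5,5183,6.16,2.06,18.41,6.13,13.83,insert
Ear and labyrinth disorders,Vertigo,4,1519,2,5186,6.83,1.25,37.32,6.81,6.62,novel
Gastrointestinal disorders,Nausea,47,1476,68,5120,2.4,1.65,3.49,2.35,22.03,trial
Gastrointestinal disorders,Abdominal pain upper,15,1508,23,5165,2.23,1.16,4.29,2.22,6.13,novel
Gastrointestinal disorders,Abdominal pain,9,1514,13,5175,2.37,1.01,5.55,2.36,4.17,novel
Gastrointestinal disorders,Abdominal pain lower,5,1518,1,5187,17.08,1.99,146.35,17.03,12.59,novel
Gastrointestinal disorders,Retching,4,1519,2,5186,6.83,1.25,37.32,6.81,6.62,novel
General disorders and administration site conditions,Fatigue,96,1427,142,5046,2.39,1.83,3.12,2.3,43.78,trial
General disorders and administration site conditions,Pain,25,1498,15,5173,5.76,3.03,10.94,5.68,36.34,novel
General disorders and administration site conditions,Oedema peripheral,22,1501,22,5166,3.44,1.9,6.23,3.41,18.82,insert
General disorders and administration site conditions,Feeling abnormal,18,1505,20,5168,3.09,1.63,5.86,3.07,13.26,novel
General disorders and administration site conditions,Chills,6,1517,2,5186,10.26,2.07,50.87,10.22,12.49,novel
General disorders and administration site conditions,Gait disturbance,4,1519,3,5185,4.55,1.02,20.36,4.54,4.74,novel
General disorders and administration site conditions,Influenza like illness,3,1520,1,5187,10.24,1.06,98.49,10.22,6.24,novel
Infections and infestations,Nasopharyngitis,19,1504,30,5158,2.17,1.22,3.87,2.16,7.28,trial
Investigations,Blood pressure decreased,28,1495,11,5177,8.81,4.38,17.75,8.67,53.91,insert
Investigations,Blood creatinine increased,18,1505,22,5166,2.81,1.5,5.25,2.79,11.41,trial
Investigations,Glomerular filtration rate decreased,17,1506,27,5161,2.16,1.17,3.97,2.14,6.42,insert
Investigations,Blood pressure abnormal,9,1514,8,5180,3.85,1.48,9.99,3.83,8.89,trial
Investigations,Hepatic enzyme increased,9,1514,1,5187,30.83,3.9,243.58,30.66,25.86,insert
Investigations,Blood potassium increased,8,1515,8,5180,3.42,1.28,9.13,3.41,6.82,insert
Investigations,Protein total decreased,5,1518,2,5186,8.54,1.66,44.07,8.52,9.49,novel
Metabolism and nutrition disorders,Gout,6,1517,3,5185,6.84,1.71,27.37,6.81,9.93,trial
Musculoskeletal and connective tissue disorders,Arthralgia,15,1508,25,5163,2.05,1.08,3.91,2.04,5.03,trial
Nervous system disorders,Dizziness,108,1415,83,5105,4.69,3.51,6.29,4.43,128.4,insert
Nervous system disorders,Somnolence,25,1498,34,5154,2.53,1.5,4.25,2.5,13.14,novel
Nervous system disorders,Loss of consciousness,3,1520,1,5187,10.24,1.06,98.49,10.22,6.24,novel
"Respiratory, thoracic and mediastinal disorders",Nasal congestion,8,1515,2,5186,13.69,2.9,64.55,13.63,18.75,novel
Skin and subcutaneous tissue disorders,Pruritus,16,1507,22,5166,2.49,1.31,4.76,2.48,8.21,trial
Vascular disorders,Hypotension,30,1493,8,5180,13.01,5.95,28.44,12.77,68.93,insert
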