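pt,s_events,s_ror,s_mortality,s_ime_dme,s_plausibility,total,band
Influenza like illness,0,0,0,0,0,0,weak
Gait disturbance,0,0,0,0,0,0,weak
Vertigo,0,0,0,0,0,0,weak
Retching,0,0,0,0,0,0,weak
Protein total decreased,0,0,0,0,0,0,weak
Abdominal pain lower,0,0,0,0,0,0,weak
Abdominal pain,0,0,0,0,0,0,weak
Loss of consciousness,0,0,0,1,0,1,weak
Gout,0,0,0,0,1,1,weak
Chills,0,1,0,0,0,1,weak
Nasal congestion,0,1,0,0,0,1,weak
Blood pressure abnormal,0,0,0,0,1,1,weak
Abdominal pain upper,1,0,0,0,0,1,weak
Feeling abnormal,1,0,0,0,0,1,weak
Somnolence,1,0,0,0,0,1,weak
Blood potassium increased,0,0,0,0,2,2,weak
Arthralgia,1,0,0,0,1,2,weak
Pruritus,1,0,0,0,1,2,weak
Blood creatinine increased,1,0,0,0,1,2,weak
Nasopharyngitis,1,0,0,0,1,2,weak
Pain,1,1,0,0,0,2,weak
Nausea,1,0,0,0,1,2,weak
Anaemia,0,1,0,0,2,3,weak
Hepatic enzyme increased,0,1,0,0,2,3,weak
Glomerular filtration rate decreased,1,0,0,0,2,3,weak
Oedema peripheral,1,0,0,0,2,3,weak
Fatigue,2,0,0,0,1,3,weak
Blood pressure decreased,1,1,0,0,2,4,weak
Hypotension,1,2,0,0,2,5,moderate
Dizziness,2,1,0,0,2,5,moderate
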