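pt,soc
COVID-19,Infections and infestations
Disease Recurrence,General disorders and administration site conditions
Dysgeusia,Nervous system disorders
Diarrhoea,Gastrointestinal disorders
Nausea,Gastrointestinal disorders
Cough,"Respiratory, thoracic and mediastinal disorders"
Fatigue,General disorders and administration site conditions
Headache,Nervous system disorders
Nasal Congestion,"Respiratory, thoracic and mediastinal disorders"
Oropharyngeal Pain,"Respiratory, thoracic and mediastinal disorders"
Rhinorrhoea,"Respiratory, thoracic and mediastinal disorders"
Pyrexia,General disorders and administration site conditions
Vomiting,Gastrointestinal disorders
Incorrect Dose Administered,"Injury, poisoning and procedural complications"
Malaise,General disorders and administration site conditions
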