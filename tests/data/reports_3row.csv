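case_id,suspect_products,suspect_ingredients,concomitant_products,reactions,sex,age_years,reporter_type,country,event_date,outcomes
A001,Nirmatrelvir|Ritonavir,nirmatrelvir|ritonavir,Atorvastatin,Disease Recurrence|Dysgeusia,female,52,consumer,US,2022-05-01,non_serious
A002,Veklury,remdesivir,,Nausea,male,abc,healthcare_professional,US,2022-04-15,hospitalization|other
A003,Sotrovimab,sotrovimab,Metformin|Aspirin,Headache,,,,,,
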