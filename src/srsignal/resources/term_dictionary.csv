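raw_term,pt,soc
Extrapyramidal disorder,Extrapyramidal disorder,Nervous system disorders
EPS symptoms,Extrapyramidal disorder,Nervous system disorders
extrapyramidal reaction,Extrapyramidal disorder,Nervous system disorders
Akathisia,Akathisia,Nervous system disorders
Constipation,Constipation,Gastrointestinal disorders
Drooling,Drooling,Gastrointestinal disorders
hypersalivation,Drooling,Gastrointestinal disorders
White blood cell count decreased,White blood cell count decreased,Investigations
WBC decreased,White blood cell count decreased,Investigations
Tremor,Tremor,Nervous system disorders
Somnolence,Somnolence,Nervous system disorders
Hepatic function abnormal,Hepatic function abnormal,Hepatobiliary disorders
liver enzymes raised,Hepatic function abnormal,Hepatobiliary disorders
Dizziness,Dizziness,Nervous system disorders
Tachycardia,Tachycardia,Cardiac disorders
Dystonia,Dystonia,Nervous system disorders
Insomnia,Insomnia,Psychiatric disorders
Orthostatic hypotension,Orthostatic hypotension,Vascular disorders
Tongue induration,Tongue induration,Gastrointestinal disorders
Blood pressure decreased,Blood pressure decreased,Investigations
Pruritus,Pruritus,Skin and subcutaneous tissue disorders
Obesity,Obesity,Metabolism and nutrition disorders
Pollakiuria,Pollakiuria,Renal and urinary disorders
Rash,Rash,Skin and subcutaneous tissue disorders
Nuchal rigidity,Nuchal rigidity,Musculoskeletal and connective tissue disorders
Dyspnoea,Dyspnoea,"Respiratory, thoracic and mediastinal disorders"
Urinary incontinence,Urinary incontinence,Renal and urinary disorders
Weight increased,Weight increased,Investigations
Nausea,Nausea,Gastrointestinal disorders
Vomiting,Vomiting,Gastrointestinal disorders
Palpitations,Palpitations,Cardiac disorders
Electrocardiogram QT prolonged,Electrocardiogram QT prolonged,Investigations
Sinus bradycardia,Sinus bradycardia,Cardiac disorders
Hyperprolactinaemia,Hyperprolactinaemia,Endocrine disorders
Pyrexia,Pyrexia,General disorders and administration site conditions
Fatigue,Fatigue,General disorders and administration site conditions
Vision blurred,Vision blurred,Eye disorders
Amenorrhoea,Amenorrhoea,Reproductive system and breast disorders
Galactorrhoea,Galactorrhoea,Reproductive system and breast disorders
Headache,Headache,Nervous system disorders
Agitation,Agitation,Psychiatric disorders
Blood glucose increased,Blood glucose increased,Investigations
Dry mouth,Dry mouth,Gastrointestinal disorders
Abnormal sensation in eye,Abnormal sensation in eye,Eye disorders
Hypertonia,Hypertonia,Nervous system disorders
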