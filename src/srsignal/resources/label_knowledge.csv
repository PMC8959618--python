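generic_name,pt
risperidone,Extrapyramidal disorder
risperidone,Akathisia
risperidone,Constipation
risperidone,Somnolence
risperidone,Tremor
risperidone,Insomnia
risperidone,Weight increased
risperidone,Hyperprolactinaemia
clozapine,Extrapyramidal disorder
clozapine,Constipation
clozapine,Drooling
clozapine,Somnolence
clozapine,Tachycardia
clozapine,White blood cell count decreased
olanzapine,Extrapyramidal disorder
olanzapine,Akathisia
olanzapine,Constipation
olanzapine,Somnolence
olanzapine,Weight increased
olanzapine,Obesity
olanzapine,Dizziness
aripiprazole,Extrapyramidal disorder
aripiprazole,Akathisia
aripiprazole,Insomnia
aripiprazole,Nausea
aripiprazole,Somnolence
quetiapine,Somnolence
quetiapine,Dizziness
quetiapine,Constipation
quetiapine,Dry mouth
quetiapine,Orthostatic hypotension
quetiapine,Tachycardia
amisulpride,Extrapyramidal disorder
amisulpride,Akathisia
amisulpride,Insomnia
amisulpride,Hyperprolactinaemia
amisulpride,Amenorrhoea
ziprasidone,Extrapyramidal disorder
ziprasidone,Akathisia
ziprasidone,Somnolence
ziprasidone,Nausea
ziprasidone,Electrocardiogram QT prolonged
perospirone,Extrapyramidal disorder
perospirone,Akathisia
perospirone,Insomnia
perospirone,Somnolence
haloperidol,Extrapyramidal disorder
haloperidol,Akathisia
haloperidol,Dystonia
haloperidol,Nuchal rigidity
haloperidol,Tremor
haloperidol,Hypertonia
perphenazine,Extrapyramidal disorder
perphenazine,Akathisia
perphenazine,Dystonia
perphenazine,Tongue induration
perphenazine,Dry mouth
sulpiride,Extrapyramidal disorder
sulpiride,Insomnia
sulpiride,Hyperprolactinaemia
sulpiride,Galactorrhoea
sulpiride,Sinus bradycardia
chlorpromazine,Extrapyramidal disorder
chlorpromazine,Orthostatic hypotension
chlorpromazine,Blood pressure decreased
chlorpromazine,Pruritus
chlorpromazine,Rash
chlorpromazine,Somnolence
chlorpromazine,Dry mouth
penfluridol,Extrapyramidal disorder
penfluridol,Akathisia
penfluridol,Insomnia
chlorprothixene,Extrapyramidal disorder
chlorprothixene,Somnolence
chlorprothixene,Dry mouth
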