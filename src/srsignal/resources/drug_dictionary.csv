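raw_name,generic_name,atc_code,apd_class
risperidone,risperidone,N05AX08,atypical
RISPERDAL,risperidone,N05AX08,atypical
risperidone tablet 1mg,risperidone,N05AX08,atypical
clozapine,clozapine,N05AH02,atypical
氯氮平/clozapine tablet 25mg,clozapine,N05AH02,atypical
olanzapine,olanzapine,N05AH03,atypical
Aripiprazole,aripiprazole,N05AX12,atypical
quetiapine,quetiapine,N05AH04,atypical
quetiapine fumarate,quetiapine,N05AH04,atypical
amisulpride,amisulpride,N05AL05,atypical
ziprasidone,ziprasidone,N05AE04,atypical
perospirone,perospirone,N05AX13,atypical
haloperidol,haloperidol,N05AD01,typical
haloperidol injection,haloperidol,N05AD01,typical
perphenazine,perphenazine,N05AB03,typical
sulpiride,sulpiride,N05AL01,typical
sulpiride tablets,sulpiride,N05AL01,typical
chlorpromazine,chlorpromazine,N05AA01,typical
penfluridol,penfluridol,N05AG03,typical
chlorprothixene,chlorprothixene,N05AF03,typical
droperidol,droperidol,N05AD08,typical
benzhexol,benzhexol,N04AA01,non_apd
amantadine,amantadine,N04BB01,non_apd
aspirin,aspirin,N02BA01,non_apd
metformin,metformin,A10BA02,non_apd
vitamin B1,vitamin B1,A11DA01,non_apd
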