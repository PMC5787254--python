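kind,item,level,count,value
binary,malnutrition,,190,
binary,insomnia_anxiety,,337,
binary,social_vulnerability,,19,
binary,delirium,,334,
binary,falls,,348,
binary,ulcers,,76,
binary,polypharmacy,,474,
binary,dysphagia,,255,
binary,pain,,146,
binary,dyspnea,,69,
binary,disease_cancer,,87,
binary,disease_respiratory,,164,
binary,disease_cardiac,,352,
binary,disease_neurological,,155,
binary,disease_digestive,,68,
binary,disease_renal,,291,
binary,advanced_chronic_disease,,260,
ordinal,cognitive,none,231,
ordinal,cognitive,mild_moderate,257,
ordinal,cognitive,severe,102,
ordinal,depressive,no,306,
ordinal,depressive,yes,251,
ordinal,depressive,not_evaluable,33,
descriptor,n,,,590
descriptor,mean_age,,,86.39
descriptor,sd_age,,,5.58
descriptor,pct_women,,,57.5
descriptor,mean_barthel,,,62.81
descriptor,sd_barthel,,,29.71
descriptor,mean_iadl_deficits,,,0.85
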