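condition,icd9_prefix,weight
myocardial_infarction,410,1
congestive_heart_failure,428,1
peripheral_vascular_disease,443,1
cerebrovascular_disease,434,1
dementia,290,1
chronic_pulmonary_disease,496,1
rheumatic_disease,714,1
peptic_ulcer,531,1
mild_liver_disease,571,1
diabetes,250,1
hemiplegia,342,2
renal_disease,585,2
cancer,199,2
severe_liver_disease,572,3
metastatic_tumour,196,6
hiv,042,6
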