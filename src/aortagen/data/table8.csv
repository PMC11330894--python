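study_id,modality,age_note,label,n,symbol,value,unit,verified
demertzis,CT,69.4+/-9.9,all,92,alpha1,84.79,deg,false
demertzis,CT,69.4+/-9.9,all,83,alpha2,73.9,deg,false
demertzis,CT,69.4+/-9.9,all,92,alpha3,70.16,deg,false
recruited,CT,72.75+/-9.32,all,3,alpha1,84.0,deg,false
recruited,CT,72.75+/-9.32,all,3,alpha2,57.0,deg,false
recruited,CT,72.75+/-9.32,all,3,alpha3,59.0,deg,false
recruited,CT,72.75+/-9.32,all,1,alphab1,80.0,deg,false
recruited,CT,72.75+/-9.32,all,1,alphab2,65.0,deg,false
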