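study_id,modality,age_note,label,n,symbol,value,unit,verified
redheuil,MRI,20-70,all,100,H,3.83,cm,false
redheuil,MRI,20-70,all,100,W,6.87,cm,false
redheuil,MRI,20-70,all,100,hw_ratio,0.56,dimensionless,false
craiem_2012,CTA,34-88,all,51,H,4.2,cm,true
craiem_2012,CTA,34-88,all,51,W,8.3,cm,true
craiem_2012,CTA,34-88,all,51,hw_ratio,0.51,dimensionless,true
alhafez,CT,BAV and TAV sub-cohorts,all,354,H,4.1,cm,false
alhafez,CT,BAV and TAV sub-cohorts,all,354,W,8.2,cm,false
alhafez,CT,BAV and TAV sub-cohorts,all,354,hw_ratio,0.5,dimensionless,false
recruited,CT,72.75+/-9.32,all,4,H,4.0,cm,true
recruited,CT,72.75+/-9.32,all,4,W,8.6,cm,true
recruited,CT,72.75+/-9.32,all,4,hw_ratio,0.47,dimensionless,true
recruited,CT,72.75+/-9.32,all,4,R,12.2,cm,true
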