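study_id,modality,age_note,label,n,symbol,value,unit,verified
vasava_cfd,CTA,young patient,all,1,L,1.8,cm,true
recruited,CT,72.75+/-9.32,all,4,L,2.8,cm,true
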