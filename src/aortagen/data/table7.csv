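study_id,modality,age_note,label,n,symbol,value,unit,verified
gupta_sodhi,Cadaver,68,all,100,d1,1.54,cm,true
gupta_sodhi,Cadaver,68,all,100,d2,3.02,cm,true
gupta_sodhi,Cadaver,68,all,100,d3,2.51,cm,true
finlay,CT,68,all,45,a,7.77,cm,true
finlay,CT,68,all,45,d1,1.83,cm,true
finlay,CT,68,all,45,d2,4.74,cm,true
wilbring,CT,63+/-15,all,118,a,7.7,cm,true
wilbring,CT,63+/-15,all,118,d1,1.69,cm,true
wilbring,CT,63+/-15,all,118,d2,3.31,cm,true
liu,CT,53.3+/-14.4,all,114,a,7.82,cm,true
zubair,CT,77.4+/-10,all,116,a,6.59,cm,true
zubair,CT,77.4+/-10,all,116,d1,1.83,cm,true
zubair,CT,77.4+/-10,all,116,d2,3.68,cm,true
saade,CT,69+/-13.5,all,75,a,8.73,cm,true
zerebiec,CT,62,all,100,d1,1.56,cm,true
zerebiec,CT,62,all,100,d2,3.17,cm,true
recruited,CT,72.75+/-9.32,all,4,a,7.5,cm,false
recruited,CT,72.75+/-9.32,all,3,d1,1.73,cm,false
recruited,CT,72.75+/-9.32,all,3,d2,3.47,cm,false
recruited,CT,72.75+/-9.32,all,1,d3,4.0,cm,false
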