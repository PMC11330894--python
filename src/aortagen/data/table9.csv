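study_id,modality,age_note,label,n,symbol,value,unit,verified
cavalcanti,Cadaver,,all,51,C1,2.9,mm,true
cavalcanti,Cadaver,,all,51,C2,3.75,mm,true
mehrotra,QCA,"49.4+/-11.22, Indian population",all,321,C1,3.1,mm,true
mehrotra,QCA,"49.4+/-11.22, Indian population",all,321,C2,4.28,mm,true
raut,QCA,51.7+/-9.35,all,229,C1,1.83,mm,true
raut,QCA,51.7+/-9.35,all,229,C2,2.34,mm,true
recruited,CT,72.75+/-9.32,all,4,C1,2.0,mm,true
recruited,CT,72.75+/-9.32,all,4,C2,2.0,mm,true
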