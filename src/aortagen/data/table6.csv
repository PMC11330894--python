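study_id,modality,age_note,label,n,symbol,value,unit,verified
gupta_sodhi,Cadaver,40-70,all,77,phi1,0.87,cm,false
gupta_sodhi,Cadaver,40-70,all,77,phi2,0.61,cm,false
gupta_sodhi,Cadaver,40-70,all,77,phi3,0.67,cm,false
gupta_sodhi,Cadaver,40-70,all,10,phib1,1.65,cm,false
gupta_sodhi,Cadaver,40-70,all,10,phib2,0.73,cm,false
shin,CT,adult,all,25,phi1,1.83,cm,true
shin,CT,adult,all,25,phi2,0.98,cm,true
shin,CT,adult,all,25,phi3,1.06,cm,true
alsaif_ramadan,CT,adult,all,36,phi1,1.79,cm,true
alsaif_ramadan,CT,adult,all,36,phi2,0.977,cm,true
alsaif_ramadan,CT,adult,all,36,phi3,1.43,cm,true
vasava_ct,CT,adult,all,1,phi1,0.88,cm,true
vasava_ct,CT,adult,all,1,phi2,0.85,cm,true
vasava_ct,CT,adult,all,1,phi3,0.99,cm,true
rengier,CT,,all,20,phi1,1.47,cm,true
rengier,CT,,all,20,phi2,0.98,cm,true
rengier,CT,,all,20,phi3,1.22,cm,true
finlay,CT,,all,45,phi1,1.57,cm,true
finlay,CT,,all,45,phi2,1.01,cm,true
finlay,CT,,all,45,phi3,1.35,cm,true
carr,CT,>=65,all,10,phi1,1.35,cm,true
carr,CT,>=65,all,10,phi2,0.75,cm,true
carr,CT,>=65,all,10,phi3,1.03,cm,true
manole,CT,,all,33,phi1,1.08,cm,false
manole,CT,,all,33,phi2,0.62,cm,false
manole,CT,,all,33,phi3,0.95,cm,false
osorio,CT,adult,all,1,phi1,1.24,cm,true
osorio,CT,adult,all,1,phi2,0.74,cm,true
osorio,CT,adult,all,1,phi3,0.74,cm,true
wilbring,CT,63+/-15,all,118,phi1,2.05,cm,true
wilbring,CT,63+/-15,all,118,phi2,1.38,cm,true
wilbring,CT,63+/-15,all,118,phi3,1.43,cm,true
zubair,CT,77.4+/-10,all,116,phi1,1.69,cm,true
zubair,CT,77.4+/-10,all,116,phi2,1.17,cm,true
zubair,CT,77.4+/-10,all,116,phi3,1.32,cm,true
tapia_nanez,CT,52.7+/-17.6,all,220,phi1,1.28,cm,false
tapia_nanez,CT,52.7+/-17.6,all,220,phi2,0.86,cm,false
tapia_nanez,CT,52.7+/-17.6,all,220,phi3,1.08,cm,false
tapia_nanez,CT,52.7+/-17.6,all,30,phib1,2.21,cm,false
tapia_nanez,CT,52.7+/-17.6,all,30,phib2,1.18,cm,false
recruited,CT,72.75+/-9.32,all,3,phi1,1.25,cm,false
recruited,CT,72.75+/-9.32,all,3,phi2,0.93,cm,false
recruited,CT,72.75+/-9.32,all,3,phi3,1.35,cm,false
recruited,CT,72.75+/-9.32,all,1,phib1,2.0,cm,false
recruited,CT,72.75+/-9.32,all,1,phib2,1.58,cm,false
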