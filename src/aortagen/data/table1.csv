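study_id,modality,age_note,label,n,symbol,value,unit,verified
nelson_sparks,Cadaver,adult (male cohort),all,193,type_i,94.3,%,true
nelson_sparks,Cadaver,adult (male cohort),all,193,type_ii,1.03,%,true
nelson_sparks,Cadaver,adult (male cohort),all,193,type_iii,3.1,%,true
nayak,CT,45-79,all,62,type_i,91.4,%,true
nayak,CT,45-79,all,62,type_ii,4.8,%,true
nayak,CT,45-79,all,62,type_iii,1.6,%,true
natsis,DSA,19-79,male,447,type_i,83.0,%,true
natsis,DSA,19-79,male,447,type_ii,15.0,%,true
natsis,DSA,19-79,male,447,type_iii,0.79,%,true
natsis,DSA,19-79,female,186,type_i,83.0,%,true
natsis,DSA,19-79,female,186,type_ii,15.0,%,true
natsis,DSA,19-79,female,186,type_iii,0.79,%,true
jakanani_adair,CT,,all,643,type_i,74.0,%,true
jakanani_adair,CT,,all,643,type_ii,20.0,%,true
jakanani_adair,CT,,all,643,type_iii,6.0,%,true
celikyay,CT,,all,1136,type_i,74.7,%,true
celikyay,CT,,all,1136,type_ii,21.1,%,true
celikyay,CT,,all,1136,type_iii,2.9,%,true
dumfarth,MSCTA,,all,361,type_i,78.12,%,true
dumfarth,MSCTA,,all,361,type_ii,11.36,%,true
dumfarth,MSCTA,,all,361,type_iii,2.22,%,true
huapaya,CT,,all,556,type_i,66.5,%,true
huapaya,CT,,all,556,type_ii,24.6,%,true
huapaya,CT,,all,556,type_iii,6.3,%,true
popieluszko,Review,systematic review of 51 articles,all,23882,type_i,80.9,%,true
popieluszko,Review,systematic review of 51 articles,all,23882,type_ii,13.6,%,true
popieluszko,Review,systematic review of 51 articles,all,23882,type_iii,2.8,%,true
recruited,CT,72.75+/-9.32,all,4,type_i,75.0,%,true
recruited,CT,72.75+/-9.32,all,4,type_ii,25.0,%,true
recruited,CT,72.75+/-9.32,all,4,type_iii,0.0,%,true
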