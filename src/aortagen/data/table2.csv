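study_id,modality,age_note,label,n,symbol,value,unit,verified
hager,CT,17-89,male,46,root_diameter,3.04,cm,true
hager,CT,17-89,male,46,D1,3.2,cm,true
hager,CT,17-89,male,46,D2,2.85,cm,true
hager,CT,17-89,male,46,proximal_descending_diameter,2.55,cm,true
hager,CT,17-89,male,46,D3,2.51,cm,true
hager,CT,17-89,female,24,root_diameter,2.88,cm,true
hager,CT,17-89,female,24,D1,2.9,cm,true
hager,CT,17-89,female,24,D2,2.63,cm,true
hager,CT,17-89,female,24,proximal_descending_diameter,2.32,cm,true
hager,CT,17-89,female,24,D3,2.27,cm,true
wolak,CT,55+/-10.2,all,4039,root_diameter,,cm,true
wolak,CT,55+/-10.2,all,4039,D1,3.3,cm,true
wolak,CT,55+/-10.2,all,4039,D2,,cm,true
wolak,CT,55+/-10.2,all,4039,proximal_descending_diameter,2.4,cm,true
wolak,CT,55+/-10.2,all,4039,D3,,cm,true
biaggi,TTE,20-80,male,815,root_diameter,3.4,cm,true
biaggi,TTE,20-80,male,815,D1,3.2,cm,true
biaggi,TTE,20-80,male,815,D2,,cm,true
biaggi,TTE,20-80,male,815,proximal_descending_diameter,,cm,true
biaggi,TTE,20-80,male,815,D3,,cm,true
biaggi,TTE,20-80,female,984,root_diameter,3.1,cm,true
biaggi,TTE,20-80,female,984,D1,3.0,cm,true
biaggi,TTE,20-80,female,984,D2,,cm,true
biaggi,TTE,20-80,female,984,proximal_descending_diameter,,cm,true
biaggi,TTE,20-80,female,984,D3,,cm,true
evangelista,Echo,,all,187,root_diameter,2.9,cm,true
evangelista,Echo,,all,187,D1,2.9,cm,true
evangelista,Echo,,all,187,D2,2.9,cm,true
evangelista,Echo,,all,187,proximal_descending_diameter,2.5,cm,true
evangelista,Echo,,all,187,D3,2.5,cm,true
redheuil,MRI,20-70,male,45,root_diameter,,cm,true
redheuil,MRI,20-70,male,45,D1,3.1,cm,true
redheuil,MRI,20-70,male,45,D2,,cm,true
redheuil,MRI,20-70,male,45,proximal_descending_diameter,2.4,cm,true
redheuil,MRI,20-70,male,45,D3,2.25,cm,true
redheuil,MRI,20-70,female,55,root_diameter,,cm,true
redheuil,MRI,20-70,female,55,D1,3.0,cm,true
redheuil,MRI,20-70,female,55,D2,,cm,true
redheuil,MRI,20-70,female,55,proximal_descending_diameter,2.2,cm,true
redheuil,MRI,20-70,female,55,D3,2.1,cm,true
craiem_2012,CTA,34-88,all,51,root_diameter,,cm,true
craiem_2012,CTA,34-88,all,51,D1,2.98,cm,true
craiem_2012,CTA,34-88,all,51,D2,2.61,cm,true
craiem_2012,CTA,34-88,all,51,proximal_descending_diameter,2.27,cm,true
craiem_2012,CTA,34-88,all,51,D3,2.27,cm,true
davis,CMR,19-70,male,208,root_diameter,2.5,cm,true
davis,CMR,19-70,male,208,D1,2.7,cm,true
davis,CMR,19-70,male,208,D2,,cm,true
davis,CMR,19-70,male,208,proximal_descending_diameter,2.1,cm,true
davis,CMR,19-70,male,208,D3,,cm,true
davis,CMR,19-70,female,239,root_diameter,2.2,cm,true
davis,CMR,19-70,female,239,D1,2.6,cm,true
davis,CMR,19-70,female,239,D2,,cm,true
davis,CMR,19-70,female,239,proximal_descending_diameter,1.9,cm,true
davis,CMR,19-70,female,239,D3,,cm,true
vizzardi,Echo,,male,495,root_diameter,2.63,cm,true
vizzardi,Echo,,male,495,D1,2.59,cm,true
vizzardi,Echo,,male,495,D2,2.59,cm,true
vizzardi,Echo,,male,495,proximal_descending_diameter,,cm,true
vizzardi,Echo,,male,495,D3,,cm,true
vizzardi,Echo,,female,507,root_diameter,2.4,cm,true
vizzardi,Echo,,female,507,D1,3.39,cm,true
vizzardi,Echo,,female,507,D2,2.44,cm,true
vizzardi,Echo,,female,507,proximal_descending_diameter,,cm,true
vizzardi,Echo,,female,507,D3,,cm,true
guo,CTA,"58.2+/-17.9, Chinese population",all,56,root_diameter,,cm,false
guo,CTA,"58.2+/-17.9, Chinese population",all,56,D1,3.2,cm,false
guo,CTA,"58.2+/-17.9, Chinese population",all,56,D2,2.73,cm,false
guo,CTA,"58.2+/-17.9, Chinese population",all,56,proximal_descending_diameter,2.54,cm,false
guo,CTA,"58.2+/-17.9, Chinese population",all,56,D3,2.47,cm,false
craiem_2016,CT,58+/-9,all,200,root_diameter,,cm,true
craiem_2016,CT,58+/-9,all,200,D1,3.0,cm,true
craiem_2016,CT,58+/-9,all,200,D2,2.6,cm,true
craiem_2016,CT,58+/-9,all,200,proximal_descending_diameter,2.3,cm,true
craiem_2016,CT,58+/-9,all,200,D3,2.3,cm,true
zubair,CT,77.4+/-10,all,116,root_diameter,3.08,cm,true
zubair,CT,77.4+/-10,all,116,D1,3.52,cm,true
zubair,CT,77.4+/-10,all,116,D2,3.05,cm,true
zubair,CT,77.4+/-10,all,116,proximal_descending_diameter,2.6,cm,true
zubair,CT,77.4+/-10,all,116,D3,2.63,cm,true
recruited,CT,72.75+/-9.32,all,4,root_diameter,3.05,cm,true
recruited,CT,72.75+/-9.32,all,4,D1,3.2,cm,true
recruited,CT,72.75+/-9.32,all,4,D2,2.7,cm,true
recruited,CT,72.75+/-9.32,all,4,proximal_descending_diameter,2.7,cm,true
recruited,CT,72.75+/-9.32,all,4,D3,2.4,cm,true
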