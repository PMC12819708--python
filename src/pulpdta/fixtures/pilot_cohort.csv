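patient_id,hs_crp_mg_l,below_lod,vas_cm,pain_category,tooth_type
P01,0.0,1,2.0,1,premolar
P02,0.0,1,3.0,1,incisor
P03,0.0,1,5.0,2,molar
P04,0.0,1,5.5,2,premolar
P05,1.0,0,6.0,2,molar
P06,3.0,0,6.5,2,molar
P07,8.0,0,7.0,2,premolar
P08,3.45,0,8.0,3,molar
P09,3.6,0,8.5,3,molar
P10,4.0,0,9.0,3,premolar
P11,5.5,0,9.0,3,molar
P12,9.0,0,9.5,3,molar
P13,18.0,0,10.0,3,molar
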