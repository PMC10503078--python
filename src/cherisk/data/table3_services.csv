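code,description,disease_id,disease_group,unit_cost_li,unit_cost_lmi
HC42,Acute pharyngitis treatment,childhood_health,childhood,0.17,0.24
C7,Intermittent preventive treatment (pregnancy),malaria,infectious_parasitic,0.45,1.02
HC8,HIV & syphilis PMTCT,hiv_aids_sti,infectious_parasitic,176.35,313.51
HC12,Diagnosis & treatment of infections (IMCI),diarrheal_diseases,infectious_parasitic,4.79,10.29
HC13,ART and viral load monitoring,hiv_aids_sti,infectious_parasitic,71.45,121.57
HC17,Syndromic management of STIs,hiv_aids_sti,infectious_parasitic,5.67,10.69
HC23,"HIV, STIs, hepatitis testing, and counseling",hiv_aids_sti,infectious_parasitic,4.31,6.08
HC27,Diagnosis and treatment of TB,tuberculosis,infectious_parasitic,135.09,175.65
HC30,Management and referrals for fever (IMAI),other_infectious_parasitic,infectious_parasitic,3.11,6.83
HC38,Aspirin for acute myocardial infarction,cardiovascular,ncd,0.03,0.05
HC40,Screening and management of diabetes,endocrine_metabolic,ncd,64.16,92.52
HC43,Management of ischemic heart disease,cardiovascular,ncd,83.97,190.17
HC44,Management of heart failure,cardiovascular,ncd,249.96,342.48
HC47,Palliative care,other_ncd,ncd,64.63,21.32
HC49,Management of bipolar disorder,mental_neurological,ncd,184.57,365.39
HC50,Management of depression,mental_neurological,ncd,16.11,48.02
HC51,Management of epilepsy,mental_neurological,ncd,27.53,53.73
HC52,Management of schizophrenia,mental_neurological,ncd,99.43,329.34
HC66,Psychosocial support and counseling,mental_neurological,ncd,64.63,21.32
C5,Antenatal tetanus immunization,maternal_conditions,reproductive,0.39,0.44
C13,Cotrimoxazole for HIV-exposed children,perinatal_conditions,reproductive,6.55,11.95
HC1,Antibiotics for neonatal pneumonia,perinatal_conditions,reproductive,6.22,6.61
HC2,Post-abortion care,maternal_conditions,reproductive,4.54,8.23
HC3,Treatment of premature membrane rupture,maternal_conditions,reproductive,4.04,4.66
HC4,Contraceptives,family_planning,reproductive,4.97,10.32
HC5,Kangaroo mother care counseling,perinatal_conditions,reproductive,2.33,4.61
HC6,"Neonatal sepsis, pneumonia, meningitis",perinatal_conditions,reproductive,2.66,3.51
HC7,Medical abortion,maternal_conditions,reproductive,4.81,5.52
HC11,Basic emergency newborn and obstetric care,maternal_conditions,reproductive,69.14,145.10
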