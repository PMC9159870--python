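characteristic,category,count
Age,<36,97
Age,>=36,40
Parity,0,78
Parity,>=1,59
Location,UO,109
Location,BO,28
Tumor diameter,<7,26
Tumor diameter,>=7,111
GA of detection,Prepregnancy,12
GA of detection,1st trimester,34
GA of detection,2nd trimester,39
GA of detection,3rd trimester,52
Symptoms,Abdominal pain,23
Symptoms,Asymptomatic,114
GA of surgery,1st trimester,25
GA of surgery,2nd trimester,56
GA of surgery,3rd trimester,51
GA of surgery,Postpartum,5
Delivery mode,Elective abortion,36
Delivery mode,Transvaginal,12
Delivery mode,CS,89
Pregnancy outcome,Miscarriage,38
Pregnancy outcome,Preterm,27
Pregnancy outcome,Full-term,72
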