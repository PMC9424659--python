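label,age_years,weight_kg,bmi,age_group,dose_mg_per_kg,source,metric,observed,predicted
child 12-17 y 4 mg/kg single,15,70.6,22.8,12-17,4,literature,AUC,374.4,386.42
child 12-17 y 4 mg/kg single,15,70.6,22.8,12-17,4,literature,CMAX,50,54.24
child 7-11 y 4 mg/kg single,10,39.7,19.1,7-11,4,literature,AUC,271,282.25
child 7-11 y 4 mg/kg single,10,39.7,19.1,7-11,4,literature,CMAX,48,52.08
child 2-6 y 4 mg/kg single,5,18,15.68,2-6,4,literature,AUC,215.3,194.92
child 2-6 y 4 mg/kg single,5,18,15.68,2-6,4,literature,CMAX,43.8,47.15
child 12-17 y 5 mg/kg label,15,70.6,22.8,12-17,5,label,AUC,434,487.16
child 12-17 y 5 mg/kg label,15,70.6,22.8,12-17,5,label,CMAX,76.4,68.38
child 7-11 y 7 mg/kg label,10,39.7,19.1,7-11,7,label,AUC,543,490.41
child 7-11 y 7 mg/kg label,10,39.7,19.1,7-11,7,label,CMAX,92.4,90.49
child 2-6 y 9 mg/kg label,5,18,15.68,2-6,9,label,AUC,452,438.36
child 2-6 y 9 mg/kg label,5,18,15.68,2-6,9,label,CMAX,90.3,90.01
child 1-2 y 10 mg/kg label,1,10.23,17.1,1-2,10,label,AUC,462,528.11
child 1-2 y 10 mg/kg label,1,10.23,17.1,1-2,10,label,CMAX,81.6,97.47
child 12-17 y 7 mg/kg label,15,70.6,22.8,12-17,7,label,AUC,656,764.9
child 12-17 y 7 mg/kg label,15,70.6,22.8,12-17,7,label,CMAX,104,104.07
child 7-11 y 9 mg/kg label,10,39.7,19.1,7-11,9,label,AUC,579,657.3
child 7-11 y 9 mg/kg label,10,39.7,19.1,7-11,9,label,CMAX,104,119.37
child 1-6 y 12 mg/kg label,5,18,15.68,1-6,12,label,AUC,620,598.1
child 1-6 y 12 mg/kg label,5,18,15.68,1-6,12,label,CMAX,106,120.91
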