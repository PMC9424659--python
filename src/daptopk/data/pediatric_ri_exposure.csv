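age_group,infection,age_years,weight_kg,bmi,dose_mg_per_kg,category,interval_h,auc_0_24,cmax
12-17,cSSSI,15,70.6,22.8,5,healthy,24,487.16,68.38
12-17,cSSSI,15,70.6,22.8,5,mild,24,478.45,63.68
12-17,cSSSI,15,70.6,22.8,5,moderate,24,526.88,56.81
12-17,cSSSI,15,70.6,22.8,5,severe,48,603.72,48.83
12-17,cSSSI,15,70.6,22.8,5,esrd,48,650.29,42.24
7-11,cSSSI,10,39.7,19.1,7,healthy,24,490.41,90.49
7-11,cSSSI,10,39.7,19.1,7,mild,24,492.74,84.07
7-11,cSSSI,10,39.7,19.1,7,moderate,24,583.18,75.63
7-11,cSSSI,10,39.7,19.1,7,severe,48,729.77,66.76
7-11,cSSSI,10,39.7,19.1,7,esrd,48,848.82,58.99
2-6,cSSSI,5,18,15.68,9,healthy,24,438.36,90.01
2-6,cSSSI,5,18,15.68,9,mild,24,446.94,82.81
2-6,cSSSI,5,18,15.68,9,moderate,24,560.18,75.36
2-6,cSSSI,5,18,15.68,9,severe,48,762.94,70.08
2-6,cSSSI,5,18,15.68,9,esrd,48,963.57,64.72
1-2,cSSSI,1,10.23,17.1,10,healthy,24,528.11,97.47
1-2,cSSSI,1,10.23,17.1,10,mild,24,550.29,89.21
1-2,cSSSI,1,10.23,17.1,10,moderate,24,679.98,80.6
1-2,cSSSI,1,10.23,17.1,10,severe,48,906.76,75.99
1-2,cSSSI,1,10.23,17.1,10,esrd,48,1125.8,71.36
12-17,bacteremia,15,70.6,22.8,7,healthy,24,683.13,95.89
12-17,bacteremia,15,70.6,22.8,7,mild,24,670.91,89.3
12-17,bacteremia,15,70.6,22.8,7,moderate,24,738.83,79.67
12-17,bacteremia,15,70.6,22.8,7,severe,48,846.58,68.47
12-17,bacteremia,15,70.6,22.8,7,esrd,48,911.89,59.22
7-11,bacteremia,10,39.7,19.1,9,healthy,24,629.77,116.2
7-11,bacteremia,10,39.7,19.1,9,mild,24,632.77,107.95
7-11,bacteremia,10,39.7,19.1,9,moderate,24,748.9,97.12
7-11,bacteremia,10,39.7,19.1,9,severe,48,937.15,85.73
7-11,bacteremia,10,39.7,19.1,9,esrd,48,1090,75.75
1-6,bacteremia,5,18,15.68,12,healthy,24,584.48,120.01
1-6,bacteremia,5,18,15.68,12,mild,24,595.92,110.41
1-6,bacteremia,5,18,15.68,12,moderate,24,746.9,100.48
1-6,bacteremia,5,18,15.68,12,severe,48,1017.3,93.44
1-6,bacteremia,5,18,15.68,12,esrd,48,1284.8,86.29
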