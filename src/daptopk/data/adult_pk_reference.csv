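label,population,physiological_status,dose_mg_per_kg,interval_h,metric,observed,predicted
adult 6 mg/kg q24h multiple-dose,adult,healthy,6,24,AUC,708.86,580
adult 6 mg/kg q24h multiple-dose,adult,healthy,6,24,CMAX,97.605,86.347
adult 8 mg/kg q24h multiple-dose,adult,healthy,8,24,AUC,742.63,772.99
adult 8 mg/kg q24h multiple-dose,adult,healthy,8,24,CMAX,108.85,115.13
adult 10 mg/kg q24h multiple-dose,adult,healthy,10,24,AUC,912.73,966.24
adult 10 mg/kg q24h multiple-dose,adult,healthy,10,24,CMAX,130.55,143.91
adult 12 mg/kg q24h multiple-dose,adult,healthy,12,24,AUC,1180,1159.5
adult 12 mg/kg q24h multiple-dose,adult,healthy,12,24,CMAX,168.39,172.69
adult 4 mg/kg q24h escalating-dose,adult,healthy,4,24,AUC,361.04,386.49
adult 4 mg/kg q24h escalating-dose,adult,healthy,4,24,CMAX,54.595,57.563
adult 6 mg/kg q24h escalating-dose,adult,healthy,6,24,AUC,587.05,579.74
adult 6 mg/kg q24h escalating-dose,adult,healthy,6,24,CMAX,86.487,86.345
adult 8 mg/kg q24h escalating-dose,adult,healthy,8,24,AUC,897.06,772.99
adult 8 mg/kg q24h escalating-dose,adult,healthy,8,24,CMAX,116.22,115.13
elderly 10 mg/kg q24h healthy,elderly_ri_cohort,healthy,10,24,AUC,854.92,961.05
elderly 10 mg/kg q24h healthy,elderly_ri_cohort,healthy,10,24,CMAX,134.57,139.04
elderly 10 mg/kg q24h mild RI,elderly_ri_cohort,mild,10,24,AUC,940,1023.1
elderly 10 mg/kg q24h mild RI,elderly_ri_cohort,mild,10,24,CMAX,138.25,137.5
elderly 10 mg/kg q24h moderate RI,elderly_ri_cohort,moderate,10,24,AUC,896.85,1087
elderly 10 mg/kg q24h moderate RI,elderly_ri_cohort,moderate,10,24,CMAX,105.55,122.54
elderly 10 mg/kg q48h severe RI,elderly_ri_cohort,severe,10,48,AUC,1403.9,1737.3
elderly 10 mg/kg q48h severe RI,elderly_ri_cohort,severe,10,48,CMAX,114.45,104.64
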