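infection,age_group,category,dose_mg_per_kg,interval_h
cSSSI,12-17,healthy,5,24
cSSSI,12-17,mild,5,24
cSSSI,12-17,moderate,5,24
cSSSI,12-17,severe,5,48
cSSSI,12-17,esrd,5,48
cSSSI,7-11,healthy,7,24
cSSSI,7-11,mild,7,24
cSSSI,7-11,moderate,7,24
cSSSI,7-11,severe,7,48
cSSSI,7-11,esrd,7,48
cSSSI,2-6,healthy,9,24
cSSSI,2-6,mild,9,24
cSSSI,2-6,moderate,9,24
cSSSI,2-6,severe,9,48
cSSSI,2-6,esrd,7,48
cSSSI,1-2,healthy,10,24
cSSSI,1-2,mild,10,24
cSSSI,1-2,moderate,10,24
cSSSI,1-2,severe,10,48
cSSSI,1-2,esrd,6,48
bacteremia,12-17,healthy,7,24
bacteremia,12-17,mild,7,24
bacteremia,12-17,moderate,7,24
bacteremia,12-17,severe,7,48
bacteremia,12-17,esrd,7,48
bacteremia,7-11,healthy,9,24
bacteremia,7-11,mild,9,24
bacteremia,7-11,moderate,9,24
bacteremia,7-11,severe,9,48
bacteremia,7-11,esrd,9,48
bacteremia,1-6,healthy,12,24
bacteremia,1-6,mild,12,24
bacteremia,1-6,moderate,12,24
bacteremia,1-6,severe,12,48
bacteremia,1-6,esrd,8,48
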