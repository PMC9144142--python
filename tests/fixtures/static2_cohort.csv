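id,age,gender,symptoms,additional_information,chronic_disease_binary,chronic_disease,outcome
P0000,46.2,male,chills,,False,,discharged
P0001,30.0,female,fatigue,"diarrhea, dizziness",True,ckd,death
P0002,40.3,female,"anosmia, dyspnea, fever",,True,"arrhythmia, ckd",death
P0003,26.4,male,"dizziness, sorethroat, sweating",fever,False,,discharged
P0004,48.3,female,rash,"fatigue, sweating",False,hepatitis,discharged
P0005,78.4,female,"anosmia, cough, nausea",sweating,True,"dementia, hypertension",death
P0006,86.5,female,sweating,myalgia,False,hepatitis,discharged
P0007,48.4,male,"fatigue, myalgia, nausea",,True,,death
P0008,44.9,female,headache,sweating,True,"asthma, copd",death
P0009,77.9,female,"anosmia, dyspnea, headache, nausea",,True,ckd,death
P0010,68.8,male,"chills, dizziness, headache","chestpain, cough",False,,discharged
P0011,90.0,female,"chestpain, dizziness, dyspnea","cough, myalgia",False,"cancer, dementia",discharged
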