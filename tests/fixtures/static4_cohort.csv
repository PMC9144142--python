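id,age,gender,symptoms,additional_information,chronic_disease_binary,chronic_disease,outcome
P0000,88.7,male,sweating,,False,"arrhythmia, dementia",stable
P0001,69.1,female,"anosmia, dyspnea, nausea",chills,False,"asthma, hypertension",discharged
P0002,74.2,female,dizziness,fatigue,False,dementia,stable
P0003,42.5,female,"chills, diarrhea",,True,,recovered
P0004,33.6,female,"fatigue, fever",,True,"diabetes, hypertension",death
P0005,46.9,male,"dizziness, rash",,False,hepatitis,stable
P0006,90.0,male,"dizziness, sweating","fatigue, fever",False,,stable
P0007,87.8,male,"chestpain, dizziness, rash, sweating",,False,hepatitis,stable
P0008,48.3,female,"cough, fatigue, fever",sweating,True,,death
P0009,35.4,female,"anosmia, dyspnea, myalgia","chills, sorethroat",False,"asthma, ckd",discharged
P0010,79.8,female,"cough, myalgia",chills,False,,discharged
P0011,90.0,female,rash,,False,arrhythmia,stable
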