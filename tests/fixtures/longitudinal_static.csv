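id,age,gender,smoke,diab,hypermed,outcome
L00000,81.8,male,True,False,False,event
L00001,48.9,female,False,True,False,event
L00002,51.4,female,True,True,False,event
L00003,51.5,male,True,False,True,no_event
L00004,56.3,female,True,False,True,no_event
L00005,77.7,female,False,True,False,event
L00006,41.9,female,False,False,True,no_event
L00007,53.3,male,True,True,True,event
L00008,47.6,male,True,True,False,event
L00009,57.9,male,False,False,True,no_event
L00010,62.9,male,False,True,True,no_event
L00011,33.6,female,False,False,True,no_event
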