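patient_id,date,kind,value,below_detection
example-001,2004-01-15,cd4,420,0
example-001,2004-01-15,viral_load,10000,0
example-001,2004-05-16,cd4,370,0
example-001,2005-01-14,haemoglobin,13.2,0
example-001,2005-02-14,cd4,420,0
example-001,2005-02-14,viral_load,50,1
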