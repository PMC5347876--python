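patient_id,date,kind
example-001,2004-10-15,start
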