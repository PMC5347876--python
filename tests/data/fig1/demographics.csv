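patient_id,gender,birth_date,ethnicity,acquisition,clinic_id,hiv_diagnosis_date,aids_diagnosis_date,admin_end_date
example-001,female,1974-06-15,black_african,heterosexual,clinic-A,2004-01-15,,2005-07-16
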