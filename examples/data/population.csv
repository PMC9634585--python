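person_id,sex,birth_date,death_date,immigration_date,emigration_date
t1,female,1985-06-01,,,
t2,male,1910-03-15,,,
t3,female,1950-01-01,2008-06-30,,
t4,male,1970-05-20,,,2010-01-01
t5,female,1960-09-09,,2003-03-01,
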