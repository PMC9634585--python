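person_id,condition_code,event_date,source
t1,mdd,2003-02-01,inpatient
t1,mdd,2004-06-01,outpatient
t1,asthma,2005-01-01,prescription
t2,ihd,2001-07-01,inpatient
t3,migraine,2002-04-15,prescription
t3,mdd,2006-01-10,emergency
t4,anxiety,1997-05-01,outpatient
t5,mdd,1998-11-20,inpatient
t5,low_back_pain,2004-08-01,outpatient
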