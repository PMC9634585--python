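condition_code,condition_class,category,state_proportion,state_dw,state_dw_lower,state_dw_upper,remission_rate,remission_rate_lower,remission_rate_upper,symptomatic_fraction,symptomatic_fraction_lower,symptomatic_fraction_upper
anxiety,MSD,mental,0.8,0.133,0.09,0.186,0.2,0.15,0.25,1,1,1
asthma,GMC,pulmonary,1,0.036,0.022,0.055,0,0,0,1,1,1
ihd,GMC,circulatory,1,0.08,0.05,0.11,0,0,0,1,1,1
low_back_pain,GMC,musculoskeletal,0.9,0.1,0.07,0.14,0,0,0,1,1,1
mdd,MSD,mental,0.3,0.145,0.099,0.209,0.5,0.4,0.6,1,1,1
mdd,MSD,mental,0.5,0.396,0.267,0.531,0.5,0.4,0.6,1,1,1
mdd,MSD,mental,0.2,0.658,0.477,0.807,0.5,0.4,0.6,1,1,1
migraine,GMC,neurological,1,0.441,0.294,0.588,0,0,0,0.085,0.058,0.112
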