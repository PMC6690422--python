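factor,contrast,case_exposed,case_unexposed,control_exposed,control_unexposed,reported_or,reported_lo,reported_hi
region,outlying vs primary service area,328,146,1215,1028,1.90,1.54,2.35
insurance_medicaid,medicaid vs insured,198,257,660,1528,1.78,1.45,2.19
insurance_none,no insurance vs insured,19,257,55,1528,2.05,1.20,3.52
financial_screen,ever vs never assessed,73,401,122,2121,3.16,2.32,4.31
education,less vs more education,231,243,740,1503,1.93,1.58,2.36
ethnicity,not white vs white,80,394,207,2036,2.00,1.51,2.64
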