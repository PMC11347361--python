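study_id,quantile,measure,point,ci_lower,ci_upper,outcome_prevalence,rare_outcome,tag
S1,Q2,rr,1.0744,0.9665,1.1943,,,owob
S1,Q3,rr,1.1319,1.0182,1.2583,,,owob
S1,Q4,rr,1.1498,1.0343,1.2782,,,owob
S2,Q2,rr,1.0247,0.9102,1.1536,,,owob
S2,Q3,rr,1.0603,0.9418,1.1937,,,owob
S2,Q4,rr,1.1094,0.9854,1.2490,,,owob
S3,Q2,rr,1.0767,0.9301,1.2465,,,owob
S3,Q3,rr,1.0877,0.9396,1.2592,,,owob
S3,Q4,rr,1.1455,0.9895,1.3261,,,owob
S4,Q2,rr,1.0093,0.9060,1.1244,,,weight
S4,Q3,rr,1.0545,0.9466,1.1747,,,weight
S4,Q4,rr,1.1139,0.9999,1.2409,,,weight
S5,Q2,rr,1.0408,0.8886,1.2190,,,weight
S5,Q3,rr,1.0701,0.9136,1.2534,,,weight
S5,Q4,rr,1.1291,0.9639,1.3224,,,weight
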