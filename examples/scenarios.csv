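name,exposure_assoc_type,exposure_assoc_value,exposure_p0,outcome_assoc_type,outcome_assoc_value,outcome_p0,provenance
depression,or,1.44,0.08,or,1.58,0.12,meta-analytic OR 1.44 for depression-exposure (p0 0.08) and OR 1.58 for depression-obesity (baseline incidence p0 0.12); converts to RR 1.39 / 1.48
overeating,r,0.28,0.5,rr,1.49,,pooled correlation 0.28 between disinhibited overeating and BMI; OR 2.88 via the SMD chain then RR at conservative p0 0.5
food_insecurity,rr,1.60,,rr,1.42,,survey RR 1.60 for food insecurity vs high exposure; meta-analytic OR 1.53 ~ RR 1.42 for obesity risk
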