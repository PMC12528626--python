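exam_id,series_id,obscured_pct,rater_categories,model_category
E0001,E0001_s0,30,r1=severe;r2=moderate;r3=severe,severe
E0001,E0001_s1,10,,mild
E0002,E0002_s0,,,optimal
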