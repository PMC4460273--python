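study_id	contrast	or	ci_low	ci_high	p
ad_meta	AG_vs_GG	1.06			0.50
ad_meta	AA_vs_GG	1.73			0.005
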