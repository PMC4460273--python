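study_id	contrast	or	ci_low	ci_high	p
zurdel_amd	AG_vs_GG	1.06			0.76
zurdel_amd	AA_vs_GG	3.03			0.01
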