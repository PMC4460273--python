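study_id	group	gg	ag	aa
leeds_amd	case	230	104	16
leeds_amd	control	2574	1092	115
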