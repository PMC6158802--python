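pattern	level
randomized controlled trial	PHASE_III_RCT
meta-analysis	META_ANALYSIS
phase iii	PHASE_III_RCT
phase ii	PHASE_II
phase i	PHASE_I
case report	CASE_REPORT
clinical series	CASE_REPORT
cell line	IN_VITRO
in vitro	IN_VITRO
mouse model	IN_VIVO
animal	IN_VIVO
in vivo	IN_VIVO
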