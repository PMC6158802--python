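level	weight
IN_VITRO	1
IN_VIVO	2
CASE_REPORT	3
PHASE_I	4
PHASE_II	5
PHASE_III_RCT	6
META_ANALYSIS	7
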