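RPS	recombination proficiency score: four DNA-repair genes	RIF1	F2R	RAD51	XRCC5
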