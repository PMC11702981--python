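gene	gene_class
GENE_ACTIVATED_001	activated
GENE_ACTIVATED_002	activated
GENE_REPRESSED_001	repressed
GENE_REPRESSED_002	repressed
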