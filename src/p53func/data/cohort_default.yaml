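# default synthetic-cohort study conditions
n_nt: 60
n_wt: 100
n_mm: 50
n_tm: 60
n_background: 853
n_activated: 116
n_repressed: 31
delta: 1.5
phi_wt_rf: 0.9
phi_mm_rf: 0.99
dispersion: 0.1
libsize_sigma: 0.2
cohort: SYN
seed: 0
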