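# Desk-scale preset: 0.1 m x 0.6 m domain, short span, small ensembles.
scenario: EXTR
precipitation: HRE
preset: desk
n_realizations: 3
base_seed: 20240
t_end_days: 20.0
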