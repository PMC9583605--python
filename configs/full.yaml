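# Reference geometry: 0.3 m x 0.9 m column (+1.1 m buffer), one year,
# 100 realizations per stochastic scenario.
scenario: EXTR
precipitation: HRE
preset: full
base_seed: 20240
# transport/reaction/profile/layers default to the reference soil registry;
# override any block here, e.g.:
# transport: {lambda_L: 0.1, lambda_T: 0.01}
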