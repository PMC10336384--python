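# Logistic-map noise sweep (SNR in dB), scaled: reps 1000 -> 64.
name: lm_noise_sweep_small
kind: sweep
system: logistic
design: noise
levels: [5, 10, 20, 30, 46]
methods: [cs, ccs]
reps: 64
L: 400
seed: 0
system_params: {C1: 0.0, C2: 0.1}
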