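# Logistic-map length sweep, scaled to 1/15 of the full 1000-realization
# benchmark so it runs in seconds (scale factor: reps 1000 -> 64).
name: lm_length_sweep_small
kind: sweep
system: logistic
design: length
levels: [100, 150, 200, 400]
methods: [cs, ccs]
reps: 64
seed: 0
system_params: {C1: 0.0, C2: 0.1}
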