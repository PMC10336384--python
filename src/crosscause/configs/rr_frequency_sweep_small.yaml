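# Rossler-Rossler frequency-ratio sweep (levels are r = omega1/omega2,
# omega1 = 1 fixed), scaled: reps 1000 -> 32.
name: rr_frequency_sweep_small
kind: sweep
system: rossler_rossler
design: frequency
levels: [0.25, 0.5, 1.0, 1.5, 2.0]
methods: [cs]
reps: 32
L: 400
seed: 0
system_params: {C: 0.1}
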