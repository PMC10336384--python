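# Rossler-Lorenz length sweep (a=6, C=2), scaled: reps 1000 -> 48.
name: rl_length_sweep_small
kind: sweep
system: rossler_lorenz
design: length
levels: [100, 200, 400]
methods: [cs]
reps: 48
seed: 0
system_params: {a: 6.0, C: 2.0}
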