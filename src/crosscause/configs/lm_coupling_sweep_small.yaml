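# Logistic-map coupling sweep over C2 (C1=0), scaled: reps 1000 -> 48.
name: lm_coupling_sweep_small
kind: sweep
system: logistic
design: coupling
# couplings beyond ~1.3 drive the map out of [0,1] for every
# initial condition, so the sweep covers the bounded regime
levels: [0.05, 0.1, 0.2, 0.5, 0.8, 1.0, 1.2]
methods: [cs, ccs]
reps: 48
L: 400
seed: 0
system_params: {C1: 0.0}
diagnostics: true
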