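# Bidirectional logistic grid, heavily scaled for a quick smoke run
# (full benchmark: 25x25 grid, 50 realizations, 100 surrogates;
# desk-scale reproduction uses 9x9 / 10 / 50).
name: lm_grid_small
kind: grid
system: logistic
methods: [cs, ccs]
grid_size: 3
reps: 2
L: 400
n_surrogates: 20
seed: 0
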