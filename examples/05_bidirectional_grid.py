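"""Bidirectional coupling grid (small smoke version).

Couplings (C1, C2) vary over a grid; per cell and direction a
stationary-bootstrap p-value is computed, and detection AUC uses 1 - p
against the ground-truth labels (coupling > 0).  The full desk-scale
benchmark uses a 9x9 grid with 10 realizations and 50 surrogates.
"""
from crosscause import grid_bidirectional

res = grid_bidirectional(methods=("cs", "ccs"), grid_size=3, reps=2,
                         L=400, n_surrogates=20, seed=0)
for method, s in res.summaries.items():
    print(f"{method:3s}: detection AUC {s.auc:.3f}; RMSE of rescaled strength "
          f"maps vs couplings: C1 {s.rmse_c1:.3f}, C2 {s.rmse_c2:.3f}, "
          f"C2-C1 {s.rmse_diff:.3f}")
print("Higher AUC = couplings detected where (and only where) they exist.")
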