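"""Score an arbitrary two-column CSV (the user-data entry point).

Any delimited text file with a header row and two numeric columns
works; this mirrors `crosscause score cs FILE --cause a --effect b`.
"""
import json

import numpy as np

from crosscause import LogisticParams, TimeSeriesSet, simulate_logistic_pair
from crosscause.experiments import score_file

ts = simulate_logistic_pair(LogisticParams(C1=0.0, C2=0.1, L=400, seed=7))
path = ts.to_csv("my_series.csv")

result = score_file(path, method="cs", channel_cause="x1",
                    channel_effect="x2", n_surrogates=50, seed=7)
fwd = result["directions"]["forward"]
rev = result["directions"]["reverse"]
print(f"forward (x1->x2): strength {fwd['score']:.4f}, p = {fwd['p_value']:.3f}")
print(f"reverse (x2->x1): strength {rev['score']:.4f}, p = {rev['p_value']:.3f}")
print(f"causality ratio r_c = {result['causality_ratio']:.1f}")
print("A significant forward score with r_c >> 1 supports x1 -> x2.")
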