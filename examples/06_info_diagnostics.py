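"""Information-theoretic diagnostics vs coupling strength.

Correlation, KSG mutual information and KL entropies flag shared
state between the two series: when |corr| and MI are large the pair is
synchronizing and directional inference becomes ill-posed.  (Couplings
beyond ~1.3 drive the printed map out of the unit interval, so the
sweep stops at the boundary of the bounded regime.)
"""
import numpy as np

from crosscause import (LogisticParams, correlation, kl_entropy, ksg_mi,
                        simulate_logistic_pair)

print(f"{'C2':>5} {'corr':>7} {'MI(nats)':>9} {'H(x1)':>7} {'H(x2)':>7}")
for C2 in (0.1, 0.3, 0.6, 1.0, 1.2):
    ts = simulate_logistic_pair(LogisticParams(C1=0.0, C2=C2, L=2000, seed=0))
    x1, x2 = ts.channel("x1"), ts.channel("x2")
    print(f"{C2:5.1f} {correlation(x1, x2):7.3f} "
          f"{max(0.0, ksg_mi(x1, x2)):9.3f} "
          f"{kl_entropy(x1):7.3f} {kl_entropy(x2):7.3f}")
print("High |corr| or MI means the pair shares state. Note the strong")
print("anti-phase locking already at C2=0.1: these near-periodic maps share")
print("structure even when weakly coupled, so raw MI needs care to interpret.")
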