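"""Simulated robustness against analytic network fragility.

Draws random services (random bipartite networks over a range of
species richness S, trait count N and connectance p), simulates
extinction sequences for each, and compares the simulated median
robustness with the closed-form prediction R_0.5 = 1 - f_0.5.
"""

import numpy as np

from fragnet import SweepSpec, fragility_sweep

spec = SweepSpec(n_services=20, n_sequences=300, seed=1)
df = fragility_sweep(spec)

cols = ["S", "N", "p_realized", "f_0.5", "R_0.5_sim"]
print(df[cols].round(3).to_string(index=False))

mad = np.mean(np.abs(df["R_0.5_sim"] - (1 - df["f_0.5"])))
print()
print(f"mean |R_0.5_sim - (1 - f_0.5)| = {mad:.3f}")
print("Reading: the simulated median robustness of each service tracks")
print("the identity line 1 - f_0.5, so fragility — computed from S, N")
print("and connectance alone — predicts how much species loss the")
print("service tolerates without simulating anything.")
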