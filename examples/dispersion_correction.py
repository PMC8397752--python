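"""Correcting fragility for non-random network structure.

Real species-to-trait networks are not Erdős–Rényi random: the number
of providers per trait can be more (overdispersed) or less
(underdispersed) variable than the binomial null S*p*q.  This script
builds a synthetic ensemble spanning both regimes, fits the
dispersion-correction slope from the residuals off R = 1 - f, and
shows the corrected fragility f* predicting robustness better than f.
"""

import numpy as np

from fragnet import (
    NetworkRecord,
    dispersion_controlled,
    summarize,
    validation_report,
)

rng = np.random.default_rng(3)
records = []
for h in (0.1, 0.3, 0.6, 1.2):          # trait-degree heterogeneity dial
    for p in (0.08, 0.15, 0.3):
        for S, N in ((60, 20), (100, 40)):
            net = dispersion_controlled(S, N, p, h, seed=rng)
            records.append(
                NetworkRecord(f"synthetic_h{h}_p{p}_{S}x{N}", "other",
                              net, summarize(net))
            )

report = validation_report(records, c=0.5, n_reps=500, seed=11)
print(f"networks analysed:        {len(report.table)}")
print(f"fitted residual slope:    {report.lambda_fitted:.3f}")
print(f"correction coefficient:   {report.lambda_correction:.3f}")
print(f"Spearman rho, R vs f:     {report.rho_uncorrected:.3f}")
print(f"Spearman rho, R vs f*:    {report.rho_corrected:.3f}")
print()
print("Reading: the fitted slope is negative — overdispersed networks")
print("(log10 d > 0) are less robust than the random-network formula")
print("predicts — and applying the correction with its magnitude makes")
print("the rank correlation between fragility and simulated robustness")
print("markedly stronger.")
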