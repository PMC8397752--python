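"""Per-species contributions to service robustness.

Because fragility depends only on local network statistics (S, N, L and
the variance of species-per-trait counts), the effect of losing one
species can be predicted without re-simulating anything.  Removing
species i with L_i links shifts richness S -> S-1, connectance

    p -> p - p * (L_i / L - 1 / S)

and, writing S̄_n = L/N for the mean providers per trait and S̄_{n_i}
for the mean taken over the traits species i possesses (species i
included in the counts), the variance of providers per trait shifts,
to first order, as

    V(S_n) -> V(S_n) + 2 * S̄_n * (S̄_n - S̄_{n_i}) * L_i / L

Chaining these through the (corrected) fragility gives the predicted
increase in f*_c were species i lost — largest for generalist providers
of uncommon traits.  The exact path actually removes the species and
recomputes; the approximations are the fast path and the exact path is
the reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .fragility import corrected_fragility, fragility_fc
from .network import NetworkSummary, SpeciesTraitNetwork, remove_species, summarize

__all__ = [
    "ContributionRecord",
    "connectance_after_removal",
    "variance_after_removal",
    "species_contribution",
    "rank_species",
    "ranking_table",
]

#: default correction coefficient (magnitude of the empirically fitted slope)
DEFAULT_LAMBDA = 1.42


@dataclass(frozen=True)
class ContributionRecord:
    """Predicted and exact effect of removing one species.

    ``delta_fstar_pred`` chains the first-order connectance/variance
    updates through fragility; ``delta_fstar_exact`` removes the
    species and recomputes (None unless the exact path was run).
    ``corrected`` records whether the dispersion correction was
    applicable (it is not when d is zero or undefined, e.g. on networks
    with no variation in providers per trait).
    """

    species_id: object
    species_index: int
    L_i: int
    mean_Sn_of_i: float
    p_after_pred: float
    var_after_pred: float
    fstar_before: float
    fstar_after_pred: float
    delta_fstar_pred: float
    fstar_after_exact: float | None = None
    delta_fstar_exact: float | None = None
    corrected: bool = True


def connectance_after_removal(summary: NetworkSummary, i: int) -> float:
    """First-order predicted connectance after removing species i."""
    if summary.S < 2:
        raise ValueError("need at least 2 species")
    if summary.L == 0:
        raise ValueError("network has no links")
    L_i = int(summary.L_i[i])
    return summary.p - summary.p * (L_i / summary.L - 1.0 / summary.S)


def variance_after_removal(net: SpeciesTraitNetwork, i: int) -> float:
    """First-order predicted variance of providers-per-trait after removing i.

    A species with no links leaves the variance unchanged (its
    mean-providers statistic is undefined).
    """
    s = summarize(net)
    L_i = int(s.L_i[i])
    if L_i == 0:
        return s.var_S_n
    traits_of_i = net.incidence[i, :].astype(bool)
    mean_Sn_of_i = float(s.S_n[traits_of_i].mean())
    return s.var_S_n + 2.0 * s.mean_S_n * (s.mean_S_n - mean_Sn_of_i) * L_i / s.L


def _fragility_with_optional_correction(
    S: int, N: int, p: float, var: float, c: float, lambda_c: float,
    use_correction: bool,
) -> tuple[float, bool]:
    """(f or f*, was_corrected). Falls back to plain f_c when d is unusable."""
    f = fragility_fc(S, N, p, c)
    if not use_correction:
        return f, False
    null = S * p * (1.0 - p)
    d = var / null if null > 0 else math.nan
    if math.isnan(d) or d <= 0.0:
        return f, False
    return corrected_fragility(f, d, lambda_c), True


def species_contribution(
    net: SpeciesTraitNetwork,
    i: int,
    c: float = 0.5,
    lambda_c: float = DEFAULT_LAMBDA,
    mode: str = "both",
    use_correction: bool = True,
) -> ContributionRecord:
    """Contribution of species i: predicted (and optionally exact) rise in f*_c.

    ``mode`` is "approx" (fast path only), "exact" or "both".  When the
    dispersion correction is inapplicable on either side (d zero or
    undefined before or after removal), plain f_c is used on both sides
    so the delta stays comparable.
    """
    if mode not in ("approx", "exact", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    s = summarize(net)
    if s.S < 2:
        raise ValueError("need at least 2 species")
    L_i = int(s.L_i[i])
    traits_of_i = net.incidence[i, :].astype(bool)
    mean_Sn_of_i = (
        float(s.S_n[traits_of_i].mean()) if L_i > 0 else math.nan
    )
    p_after = connectance_after_removal(s, i)
    var_after = variance_after_removal(net, i)

    f_before, corr_before = _fragility_with_optional_correction(
        s.S, s.N, s.p, s.var_S_n, c, lambda_c, use_correction
    )
    f_after_pred, corr_after = _fragility_with_optional_correction(
        s.S - 1, s.N, p_after, var_after, c, lambda_c, use_correction
    )
    corrected = corr_before and corr_after
    if not corrected:
        # keep both sides on the same (uncorrected) scale
        f_before = fragility_fc(s.S, s.N, s.p, c)
        f_after_pred = fragility_fc(s.S - 1, s.N, p_after, c)

    f_after_exact = None
    delta_exact = None
    if mode in ("exact", "both"):
        reduced = summarize(remove_species(net, i))
        f_after_exact, corr_exact = _fragility_with_optional_correction(
            reduced.S, reduced.N, reduced.p, reduced.var_S_n, c, lambda_c,
            use_correction and corrected,
        )
        if corrected and not corr_exact:
            # exact removal degenerated; report everything uncorrected
            corrected = False
            f_before = fragility_fc(s.S, s.N, s.p, c)
            f_after_pred = fragility_fc(s.S - 1, s.N, p_after, c)
            f_after_exact = fragility_fc(reduced.S, reduced.N, reduced.p, c)
        delta_exact = f_after_exact - f_before

    return ContributionRecord(
        species_id=net.species_ids[i],
        species_index=i,
        L_i=L_i,
        mean_Sn_of_i=mean_Sn_of_i,
        p_after_pred=p_after,
        var_after_pred=var_after,
        fstar_before=f_before,
        fstar_after_pred=f_after_pred,
        delta_fstar_pred=f_after_pred - f_before,
        fstar_after_exact=f_after_exact,
        delta_fstar_exact=delta_exact,
        corrected=corrected,
    )


def rank_species(
    net: SpeciesTraitNetwork,
    c: float = 0.5,
    lambda_c: float = DEFAULT_LAMBDA,
    mode: str = "exact",
    use_correction: bool = True,
) -> list[ContributionRecord]:
    """All species ranked by decreasing predicted fragility increase.

    ``mode`` selects which delta orders the ranking ("approx" or
    "exact"); ties break deterministically by species label.
    """
    if mode not in ("approx", "exact"):
        raise ValueError("ranking mode must be 'approx' or 'exact'")
    run_mode = "approx" if mode == "approx" else "both"
    records = [
        species_contribution(
            net, i, c=c, lambda_c=lambda_c, mode=run_mode,
            use_correction=use_correction,
        )
        for i in range(net.n_species)
    ]

    def key(r: ContributionRecord):
        delta = r.delta_fstar_pred if mode == "approx" else r.delta_fstar_exact
        return (-delta, str(r.species_id))

    return sorted(records, key=key)


def ranking_table(records: list[ContributionRecord]) -> pd.DataFrame:
    """CSV-ready ranking table."""
    return pd.DataFrame(
        {
            "species_id": [r.species_id for r in records],
            "L_i": [r.L_i for r in records],
            "mean_Sn_of_i": [r.mean_Sn_of_i for r in records],
            "delta_fstar_pred": [r.delta_fstar_pred for r in records],
            "delta_fstar_exact": [r.delta_fstar_exact for r in records],
        }
    )
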