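"""Reading empirical bipartite matrices and the validation pipeline.

Empirical interaction matrices (Web of Life CSV dialect: a header row
of labels, a leading label column, numeric counts) are binarized on
read — a count above zero becomes a link — and oriented so that rows of
the resulting network are provider species and columns are traits.
For a pollination web, for example, the pollinators are the species
and each plant is a web-level trait: the service (pollination of every
plant) is lost as soon as one plant loses its last pollinator.

Filtering follows the study protocol: networks with a single trait,
or with no variation in the number of species per trait (dispersion
undefined or zero), are excluded from validation.

:func:`validation_report` runs the full comparison: per network, the
analytic fragility, the dispersion, and the simulated robustness
percentile; then the fitted dispersion-correction slope and the
Spearman rank correlations of robustness against plain and corrected
fragility.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .boolean import and_service
from .fragility import calibrate_lambda, corrected_fragility, fragility_fc
from .network import NetworkSummary, SpeciesTraitNetwork, summarize
from .robustness import simulate_robustness

__all__ = [
    "NetworkRecord",
    "read_bipartite_csv",
    "write_bipartite_csv",
    "filter_networks",
    "ValidationReport",
    "validation_report",
]

NETWORK_TYPES = ("AF", "HP", "PA", "PH", "PL", "SD")

#: for typed webs the database convention puts the trait guild
#: (plants, hosts, anemones) in rows and the providers in columns
_DEFAULT_ORIENTATION = {t: "columns_are_species" for t in NETWORK_TYPES}


@dataclass
class NetworkRecord:
    """One empirical (or synthetic stand-in) network with its metadata."""

    name: str
    network_type: str
    net: SpeciesTraitNetwork
    summary: NetworkSummary
    excluded: bool = False
    exclusion_reason: str | None = None


def _infer_type(name: str) -> str:
    tokens = Path(name).stem.upper().replace("-", "_").split("_")
    for t in NETWORK_TYPES:
        if t in tokens:
            return t
    return "other"


def read_bipartite_csv(
    path, orientation: str | None = None, network_type: str | None = None
) -> NetworkRecord:
    """Read a labeled count matrix, binarize it and orient species vs traits.

    ``orientation`` is "rows_are_species" or "columns_are_species";
    when None it defaults by network type (providers in columns for the
    recognised empirical web types, rows otherwise).  The network type
    is inferred from the file name (e.g. ``M_PL_010.csv`` -> "PL")
    unless given.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty matrix")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: non-numeric cells in matrix")
    if np.isnan(values.astype(float)).any():
        raise ValueError(f"{path}: missing values in matrix")
    ntype = network_type if network_type is not None else _infer_type(path.name)
    if orientation is None:
        orientation = _DEFAULT_ORIENTATION.get(ntype, "rows_are_species")
    if orientation not in ("rows_are_species", "columns_are_species"):
        raise ValueError(f"unknown orientation {orientation!r}")

    binary = (values > 0).astype(np.int8)
    row_labels = [str(x) for x in df.index]
    col_labels = [str(x) for x in df.columns]
    if orientation == "columns_are_species":
        net = SpeciesTraitNetwork(tuple(col_labels), tuple(row_labels), binary.T)
    else:
        net = SpeciesTraitNetwork(tuple(row_labels), tuple(col_labels), binary)
    return NetworkRecord(
        name=path.stem, network_type=ntype, net=net, summary=summarize(net)
    )


def write_bipartite_csv(net: SpeciesTraitNetwork, path) -> None:
    """Write a network as a labeled binary CSV (rows = species)."""
    df = pd.DataFrame(
        net.incidence, index=list(net.species_ids), columns=list(net.trait_ids)
    )
    df.to_csv(path)


def filter_networks(
    records: Iterable[NetworkRecord],
) -> tuple[list[NetworkRecord], list[NetworkRecord]]:
    """Apply the exclusion rules; returns (kept, excluded).

    A network is excluded if it has a single trait, or if the number of
    species per trait shows no variation (dispersion zero/undefined).
    Each excluded record carries exactly one reason (the first rule
    that fires).  Deterministic and order-independent.
    """
    kept, excluded = [], []
    for rec in records:
        if rec.summary.N == 1:
            reason = "single trait"
        elif rec.summary.var_S_n == 0 or not rec.summary.dispersion_defined:
            reason = "no variation in species per trait"
        else:
            reason = None
        rec.excluded = reason is not None
        rec.exclusion_reason = reason
        (excluded if rec.excluded else kept).append(rec)
    return kept, excluded


@dataclass
class ValidationReport:
    """Output of the robustness-vs-fragility validation pipeline."""

    table: pd.DataFrame
    c: float
    n_reps: int
    seed: int | None
    lambda_fitted: float  # signed slope of the residual regression
    lambda_correction: float  # coefficient applied in the correction (= |slope|)
    rho_uncorrected: float
    rho_corrected: float
    per_type: pd.DataFrame

    def to_json_dict(self) -> dict:
        return {
            "c": self.c,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "n_networks": int(len(self.table)),
            "lambda_fitted": self.lambda_fitted,
            "lambda_correction": self.lambda_correction,
            "spearman_rho_uncorrected": self.rho_uncorrected,
            "spearman_rho_corrected": self.rho_corrected,
        }


def validation_report(
    records: Sequence[NetworkRecord],
    c: float = 0.5,
    n_reps: int = 1000,
    seed: int | None = 0,
) -> ValidationReport:
    """Fragility-vs-robustness validation across a set of networks.

    For each kept record: fragility f_c from (S, N, p), dispersion d,
    and the simulated robustness percentile R_c from ``n_reps``
    extinction sequences.  The correction slope lambda_c is then fitted
    from the scaled residuals, corrected fragility f*_c computed with
    its magnitude, and Spearman correlations of R_c against f_c and
    f*_c reported, along with per-type residual summaries.
    """
    kept, _ = filter_networks(list(records))
    if len(kept) < 2:
        raise ValueError("need at least 2 non-excluded networks")
    rng = np.random.default_rng(seed)
    rows = []
    for rec in kept:
        s = rec.summary
        f_c = fragility_fc(s.S, s.N, s.p, c)
        dist = simulate_robustness(rec.net, and_service(s.N), n_reps, seed=rng)
        rows.append(
            {
                "name": rec.name,
                "network_type": rec.network_type,
                "S": s.S,
                "N": s.N,
                "L": s.L,
                "p": s.p,
                "dispersion_d": s.dispersion_d,
                "log10_d": s.log10_d,
                "f_c": f_c,
                "R_c_sim": dist.percentile(c),
            }
        )
    df = pd.DataFrame(rows)

    lam_fit = calibrate_lambda(
        zip(df["R_c_sim"], df["f_c"], df["dispersion_d"])
    )
    lam_corr = abs(lam_fit)
    df["f_star_c"] = [
        corrected_fragility(f, d, lam_corr)
        for f, d in zip(df["f_c"], df["dispersion_d"])
    ]
    df["residual_uncorrected"] = df["R_c_sim"] - (1.0 - df["f_c"])
    df["residual_corrected"] = df["R_c_sim"] - (1.0 - df["f_star_c"])

    rho_f = float(stats.spearmanr(df["R_c_sim"], df["f_c"]).statistic)
    rho_fstar = float(stats.spearmanr(df["R_c_sim"], df["f_star_c"]).statistic)

    per_type = (
        df.groupby("network_type")["residual_corrected"]
        .agg(
            n="size",
            mean="mean",
            q05=lambda x: x.quantile(0.05),
            q95=lambda x: x.quantile(0.95),
        )
        .reset_index()
    )

    return ValidationReport(
        table=df,
        c=c,
        n_reps=n_reps,
        seed=seed if not isinstance(seed, np.random.Generator) else None,
        lambda_fitted=lam_fit,
        lambda_correction=lam_corr,
        rho_uncorrected=rho_f,
        rho_corrected=rho_fstar,
        per_type=per_type,
    )
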