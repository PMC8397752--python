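"""Network fragility: closed-form percentiles of the robustness distribution.

For a random species-to-trait network with S species, N traits and
connectance p (q = 1 - p), the c-th percentile of the robustness
distribution is approximated by ``R_c = 1 - f_c`` with the network
fragility

    f_c = log(1 - (1 - q^S) * exp(-c/N)) / (S * log q)

Real networks deviate from the random null; the deviation is captured
by the dispersion d (observed variance of species-per-trait counts over
the binomial null S*p*q), and fragility is corrected as

    f*_c = f_c + lambda_c * f_c * (1 - f_c) * log10(d),  lambda_c > 0

so overdispersion (d > 1) increases fragility and underdispersion
decreases it.  The coefficient lambda_c is calibrated by regressing the
scaled residuals (R_c - 1 + f_c) / (f_c (1 - f_c)) on log10(d) through
the origin; that fitted slope is negative (overdispersion lowers
robustness), and its magnitude is the lambda_c used in the correction.
Both conventions are kept explicit: :func:`calibrate_lambda` returns
the signed fitted slope, :func:`corrected_fragility` consumes the
positive coefficient (it takes |lambda_c| of whatever it is given).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "fragility_fc",
    "predicted_percentile",
    "corrected_fragility",
    "calibrate_lambda",
    "FragilityProfile",
    "fragility_profile",
]


def fragility_fc(S: int, N: int, p: float, c: float, boundary: str = "raise") -> float:
    """Network fragility f_c of a random S x N network with connectance p.

    ``boundary`` controls degenerate connectance: "raise" rejects
    p in {0, 1}; "limit" returns the documented limits f_c -> 0 as
    p -> 1 (a fully connected network is maximally robust) and
    f_c -> exp(-c/N) as p -> 0.
    """
    if S < 1 or N < 1:
        raise ValueError("S and N must be >= 1")
    if not 0.0 < c < 1.0:
        raise ValueError("percentile level c must be in (0, 1)")
    if not 0.0 < p < 1.0:
        if boundary == "limit":
            if p == 1.0:
                return 0.0
            if p == 0.0:
                return math.exp(-c / N)
        raise ValueError("connectance p must be in (0, 1)")
    log_q = math.log1p(-p)
    one_minus_qS = -math.expm1(S * log_q)  # 1 - q^S, stable for small p
    f = math.log1p(-one_minus_qS * math.exp(-c / N)) / (S * log_q)
    return f


def predicted_percentile(f: float) -> float:
    """Percentile prediction R_c = 1 - f from a fragility value."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("fragility must be in [0, 1]")
    return 1.0 - f


def corrected_fragility(
    f_c: float, d: float, lambda_c: float, simplified: bool = False
) -> float:
    """Dispersion-corrected fragility f*_c.

    Default: ``f*_c = f_c + |lambda_c| * f_c * (1 - f_c) * log10(d)``.
    With ``simplified=True`` the f(1-f) factor is dropped
    (``f*_c = f_c + |lambda_c| * log10(d)``).  The absolute value makes
    the call agnostic to whether the caller passes the positive
    correction coefficient or the signed fitted slope.
    """
    if not 0.0 < f_c < 1.0:
        raise ValueError("f_c must be in (0, 1)")
    if not (d > 0.0) or math.isnan(d):
        raise ValueError("dispersion d must be positive and defined")
    lam = abs(lambda_c)
    if simplified:
        return f_c + lam * math.log10(d)
    return f_c + lam * f_c * (1.0 - f_c) * math.log10(d)


def calibrate_lambda(records: Iterable[tuple[float, float, float]]) -> float:
    """Fit the dispersion-correction slope from (R_c_sim, f_c, d) records.

    Least-squares slope through the origin of
    y = (R_c - 1 + f_c) / (f_c (1 - f_c)) on x = log10(d).  The fitted
    slope is returned SIGNED (negative when overdispersion lowers
    robustness); the Eq.-style correction coefficient is its negation /
    absolute value.
    """
    xs, ys = [], []
    for R_c, f_c, d in records:
        if math.isnan(d) or d <= 0.0:
            continue
        if not 0.0 < f_c < 1.0:
            continue
        xs.append(math.log10(d))
        ys.append((R_c - 1.0 + f_c) / (f_c * (1.0 - f_c)))
    if len(xs) < 2:
        raise ValueError("need at least 2 usable records to calibrate lambda")
    x = np.asarray(xs)
    y = np.asarray(ys)
    sxx = float(x @ x)
    if sxx == 0.0:
        raise ValueError("all log10(d) are zero: slope undefined")
    return float(x @ y / sxx)


@dataclass(frozen=True)
class FragilityProfile:
    """Fragility and predicted robustness percentiles for a set of c levels.

    ``f_star_c`` and the correction fields are NaN-free only when a
    dispersion and coefficient were supplied; ``predicted_R_c`` uses
    the corrected fragility when available, otherwise the plain one.
    """

    S: int
    N: int
    p: float
    c_levels: tuple
    f_c: np.ndarray = field(repr=False)
    d: float = math.nan
    lambda_c: float = math.nan
    f_star_c: np.ndarray | None = field(default=None, repr=False)
    simplified: bool = False

    @property
    def corrected(self) -> bool:
        return self.f_star_c is not None

    @property
    def predicted_R_c(self) -> np.ndarray:
        f = self.f_star_c if self.corrected else self.f_c
        return 1.0 - f

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"c": self.c_levels, "f_c": self.f_c})
        if self.corrected:
            df["f_star_c"] = self.f_star_c
        df["predicted_R_c"] = self.predicted_R_c
        return df

    def to_json(self) -> str:
        out = {
            "S": self.S,
            "N": self.N,
            "p": self.p,
            "dispersion_d": None if math.isnan(self.d) else self.d,
            "lambda_c": None if math.isnan(self.lambda_c) else self.lambda_c,
            "simplified_correction": self.simplified,
            "levels": [
                {
                    "c": c,
                    "f_c": float(fc),
                    "f_star_c": (
                        float(self.f_star_c[i]) if self.corrected else None
                    ),
                    "predicted_R_c": float(self.predicted_R_c[i]),
                }
                for i, (c, fc) in enumerate(zip(self.c_levels, self.f_c))
            ],
        }
        return json.dumps(out, indent=2)


def fragility_profile(
    S: int,
    N: int,
    p: float,
    c_levels: Sequence[float] = (0.1, 0.5, 0.9),
    d: float | None = None,
    lambda_c: float | None = None,
    simplified: bool = False,
) -> FragilityProfile:
    """Compute f_c (and f*_c when d and lambda_c are given) per c level."""
    c_levels = tuple(float(c) for c in c_levels)
    f = np.array([fragility_fc(S, N, p, c) for c in c_levels])
    f_star = None
    if d is not None and lambda_c is not None:
        f_star = np.array(
            [corrected_fragility(fc, d, lambda_c, simplified=simplified) for fc in f]
        )
    return FragilityProfile(
        S=S,
        N=N,
        p=p,
        c_levels=c_levels,
        f_c=f,
        d=math.nan if d is None else float(d),
        lambda_c=math.nan if lambda_c is None else float(lambda_c),
        f_star_c=f_star,
        simplified=simplified,
    )
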