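"""Bipartite species-to-trait networks and their summary statistics.

The central object is :class:`SpeciesTraitNetwork`: a binary incidence
matrix whose rows are species (the providers) and whose columns are the
functional traits they collectively supply.  A service built on such a
network survives species removals as long as every trait retains at
least one surviving provider.

:func:`summarize` computes the handful of network statistics the whole
theory runs on: richness ``S``, trait count ``N``, links ``L``,
connectance ``p = L/(S*N)``, the per-trait provider counts ``S_n`` and
their variance, and the dispersion ``d`` — the ratio of that variance to
the binomial null ``S*p*q`` expected of a random network with the same
connectance.  ``log10(d)`` measures deviation from randomness: positive
for overdispersed (heterogeneous) trait degrees, negative for
underdispersed (near-regular) ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SpeciesTraitNetwork",
    "NetworkSummary",
    "summarize",
    "remove_species",
]


@dataclass(frozen=True)
class SpeciesTraitNetwork:
    """Binary bipartite incidence of S species (rows) x N traits (columns).

    Parameters
    ----------
    species_ids, trait_ids
        Ordered, duplicate-free labels for rows and columns.
    incidence
        (S, N) array-like of 0/1; entry 1 means the species possesses
        (provides) the trait.
    """

    species_ids: tuple
    trait_ids: tuple
    incidence: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        inc = np.asarray(self.incidence)
        if inc.ndim != 2:
            raise ValueError("incidence must be a 2-D matrix")
        if not np.isin(inc, (0, 1)).all():
            raise ValueError("incidence entries must be 0 or 1")
        inc = np.ascontiguousarray(inc, dtype=np.int8)
        inc.setflags(write=False)
        object.__setattr__(self, "incidence", inc)
        object.__setattr__(self, "species_ids", tuple(self.species_ids))
        object.__setattr__(self, "trait_ids", tuple(self.trait_ids))
        S, N = inc.shape
        if S < 1 or N < 1:
            raise ValueError("need at least one species and one trait")
        if len(self.species_ids) != S:
            raise ValueError(f"{len(self.species_ids)} species labels for {S} rows")
        if len(self.trait_ids) != N:
            raise ValueError(f"{len(self.trait_ids)} trait labels for {N} columns")
        if len(set(self.species_ids)) != S:
            raise ValueError("duplicate species labels")
        if len(set(self.trait_ids)) != N:
            raise ValueError("duplicate trait labels")

    @property
    def n_species(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_traits(self) -> int:
        return self.incidence.shape[1]

    @classmethod
    def from_matrix(
        cls,
        incidence: Sequence[Sequence[int]] | np.ndarray,
        species_ids: Sequence | None = None,
        trait_ids: Sequence | None = None,
    ) -> "SpeciesTraitNetwork":
        """Build a network from a matrix, generating labels if absent."""
        inc = np.asarray(incidence)
        S, N = inc.shape
        if species_ids is None:
            species_ids = [f"sp{i + 1}" for i in range(S)]
        if trait_ids is None:
            trait_ids = [f"tr{j + 1}" for j in range(N)]
        return cls(tuple(species_ids), tuple(trait_ids), inc)


@dataclass(frozen=True)
class NetworkSummary:
    """Summary statistics of a species-to-trait network.

    ``dispersion_d`` is NaN when the binomial null variance ``S*p*q`` is
    zero (connectance 0 or 1), where dispersion is undefined.  Variances
    use the population convention (divide by N), matching the null
    ``S*p*q`` which is an exact binomial variance.
    """

    S: int
    N: int
    L: int
    p: float
    q: float
    S_n: np.ndarray = field(repr=False)
    L_i: np.ndarray = field(repr=False)
    mean_S_n: float
    var_S_n: float
    null_var: float
    dispersion_d: float
    empty_traits: tuple = ()

    @property
    def dispersion_defined(self) -> bool:
        return not math.isnan(self.dispersion_d)

    @property
    def log10_d(self) -> float:
        """log10 of dispersion; NaN if undefined, -inf if d == 0."""
        if not self.dispersion_defined:
            return math.nan
        if self.dispersion_d == 0.0:
            return -math.inf
        return math.log10(self.dispersion_d)


def summarize(net: SpeciesTraitNetwork) -> NetworkSummary:
    """Compute all :class:`NetworkSummary` fields for a network.

    Pure and idempotent.  Degenerate connectance (p in {0, 1}) yields
    ``dispersion_d = NaN`` rather than an error.
    """
    inc = net.incidence
    S, N = inc.shape
    S_n = inc.sum(axis=0, dtype=np.int64)
    L_i = inc.sum(axis=1, dtype=np.int64)
    L = int(S_n.sum())
    p = L / (S * N)
    q = 1.0 - p
    mean_S_n = L / N
    var_S_n = float(np.var(S_n))  # population variance, ddof=0
    null_var = S * p * q
    d = var_S_n / null_var if null_var > 0 else math.nan
    empty = tuple(int(j) for j in np.flatnonzero(S_n == 0))
    return NetworkSummary(
        S=S,
        N=N,
        L=L,
        p=p,
        q=q,
        S_n=S_n,
        L_i=L_i,
        mean_S_n=mean_S_n,
        var_S_n=var_S_n,
        null_var=null_var,
        dispersion_d=d,
        empty_traits=empty,
    )


def remove_species(net: SpeciesTraitNetwork, species_index: int) -> SpeciesTraitNetwork:
    """Return a copy of ``net`` with one species (row) removed.

    All N trait columns are retained even if the removal empties them.
    Removing the last remaining species is an error.
    """
    S = net.n_species
    if not -S <= species_index < S:
        raise IndexError(f"species index {species_index} out of range for S={S}")
    if S == 1:
        raise ValueError("cannot remove the last species")
    species_index %= S
    keep = [i for i in range(S) if i != species_index]
    return SpeciesTraitNetwork(
        tuple(net.species_ids[i] for i in keep),
        net.trait_ids,
        net.incidence[keep, :],
    )
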