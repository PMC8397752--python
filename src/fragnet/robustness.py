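"""Robustness of service supply to sequential species extinctions.

For one extinction sequence (a permutation of the species), robustness
is m/S where m is the 1-based position of the removal at which the
service first evaluates to 0.  Considering all sequences at once yields
the robustness distribution R(E), a multiset supported on
{1/S, 2/S, ..., 1}; its percentiles R_c are the quantities the analytic
fragility theory predicts.

For the AND ∘ OR^N service the loss step of a sequence is simply the
first step at which some trait's provider set is exhausted, which
vectorises: the loss step equals ``min over traits of (max removal
position over that trait's providers)``.  Arbitrary truth-table
services are evaluated step by step (they need not be monotone; the
FIRST zero counts).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boolean import AND, BooleanService, _table_index
from .network import SpeciesTraitNetwork

__all__ = [
    "ServiceAlreadyLostError",
    "RobustnessDistribution",
    "robustness_of_sequence",
    "simulate_robustness",
    "enumerate_robustness",
    "percentile",
]

#: default bound on S for exhaustive enumeration (S! sequences)
ENUMERATION_BOUND = 9


class ServiceAlreadyLostError(ValueError):
    """The service evaluates to 0 at the full community."""


@dataclass(frozen=True)
class RobustnessDistribution:
    """Multiset of per-sequence robustness values for one service.

    ``values`` holds one entry per extinction sequence, each in
    {1/S, ..., 1}.  ``is_exhaustive`` marks an exact distribution over
    all S! permutations.
    """

    S: int
    values: np.ndarray = field(repr=False)
    is_exhaustive: bool = False

    def __post_init__(self) -> None:
        vals = np.sort(np.asarray(self.values, dtype=float))
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    @property
    def n_sequences(self) -> int:
        return self.values.size

    def percentile(self, c: float) -> float:
        return percentile(self, c)

    @property
    def median(self) -> float:
        return self.percentile(0.5)

    def to_frame(self) -> pd.DataFrame:
        """Two-column table (robustness value, count of sequences)."""
        vals, counts = np.unique(self.values, return_counts=True)
        return pd.DataFrame({"robustness": vals, "count": counts})

    def percentiles_json(self, c_levels=(0.1, 0.25, 0.5, 0.75, 0.9)) -> str:
        out = {
            "S": self.S,
            "n_sequences": int(self.n_sequences),
            "is_exhaustive": self.is_exhaustive,
            "percentiles": {str(c): self.percentile(c) for c in c_levels},
        }
        return json.dumps(out, indent=2)


def percentile(dist: RobustnessDistribution, c: float) -> float:
    """Lower empirical quantile R_c of the robustness multiset.

    The smallest value v such that at least a fraction c of sequences
    have robustness <= v; stays on the discrete support {m/S}.
    """
    if not 0.0 < c < 1.0:
        raise ValueError("percentile level c must be in (0, 1)")
    n = dist.n_sequences
    if n == 0:
        raise ValueError("empty robustness distribution")
    k = math.ceil(c * n)  # 1-based rank
    return float(dist.values[k - 1])


def _check_full_community(net: SpeciesTraitNetwork, service: BooleanService) -> None:
    if service.n_traits != net.n_traits:
        raise ValueError(
            f"service over {service.n_traits} traits does not match "
            f"network with {net.n_traits}"
        )
    S_n = net.incidence.sum(axis=0)
    if service.kind == AND:
        if (S_n == 0).any():
            raise ServiceAlreadyLostError(
                "some trait has no provider species: service lost at the "
                "full community"
            )
    else:
        full = (S_n > 0).astype(np.uint8)
        if not service.table[_table_index(full)]:
            raise ServiceAlreadyLostError("E* is 0 at the full community")


def _and_loss_steps(net: SpeciesTraitNetwork, perms: np.ndarray) -> np.ndarray:
    """Loss step (1-based) of each permutation row under AND ∘ OR^N."""
    n, S = perms.shape
    pos = np.empty((n, S), dtype=np.int64)
    np.put_along_axis(pos, perms, np.broadcast_to(np.arange(S), (n, S)), axis=1)
    inc = net.incidence
    steps = np.empty((n, net.n_traits), dtype=np.int64)
    for j in range(net.n_traits):
        sharers = np.flatnonzero(inc[:, j])
        steps[:, j] = pos[:, sharers].max(axis=1)
    return steps.min(axis=1) + 1


def _table_loss_step(net: SpeciesTraitNetwork, service: BooleanService, order) -> int:
    # re-evaluate E* after every removal; the FIRST zero counts
    counts = net.incidence.sum(axis=0).astype(np.int64)
    S = net.n_species
    for step, sp in enumerate(order, start=1):
        counts -= net.incidence[sp, :]
        idx = _table_index((counts > 0).astype(np.uint8))
        if not service.table[idx]:
            return step
    raise ValueError(
        "service never lost along the sequence (E* is 1 on the empty "
        "trait configuration)"
    )


def robustness_of_sequence(
    net: SpeciesTraitNetwork, service: BooleanService, order
) -> float:
    """Robustness m/S of one extinction sequence.

    ``order`` is a permutation of 0..S-1 giving the removal order; m is
    the 1-based position of the removal after which the service first
    evaluates to 0 (the causal removal is counted).
    """
    order = np.asarray(order, dtype=np.int64)
    S = net.n_species
    if sorted(order.tolist()) != list(range(S)):
        raise ValueError("order must be a permutation of 0..S-1")
    _check_full_community(net, service)
    if service.kind == AND:
        step = int(_and_loss_steps(net, order[None, :])[0])
    else:
        step = _table_loss_step(net, service, order)
    return step / S


def simulate_robustness(
    net: SpeciesTraitNetwork,
    service: BooleanService,
    n_reps: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> RobustnessDistribution:
    """Monte-Carlo estimate of R(E) from uniform-random extinction sequences.

    Draws ``n_reps`` permutations from a seeded generator; reproducible
    for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    _check_full_community(net, service)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S = net.n_species
    perms = rng.permuted(np.broadcast_to(np.arange(S), (n_reps, S)).copy(), axis=1)
    if service.kind == AND:
        steps = _and_loss_steps(net, perms)
        values = steps / S
    else:
        values = np.array(
            [_table_loss_step(net, service, row) / S for row in perms]
        )
    return RobustnessDistribution(S=S, values=values, is_exhaustive=False)


def enumerate_robustness(
    net: SpeciesTraitNetwork,
    service: BooleanService,
    max_species: int = ENUMERATION_BOUND,
) -> RobustnessDistribution:
    """Exact R(E): robustness of every one of the S! extinction sequences."""
    S = net.n_species
    if S > max_species:
        raise ValueError(
            f"S={S} exceeds the enumeration bound {max_species} "
            f"({math.factorial(S)} sequences); use simulate_robustness"
        )
    _check_full_community(net, service)
    perms = np.array(list(itertools.permutations(range(S))), dtype=np.int64)
    if service.kind == AND:
        values = _and_loss_steps(net, perms) / S
    else:
        values = np.array(
            [_table_loss_step(net, service, row) / S for row in perms]
        )
    return RobustnessDistribution(S=S, values=values, is_exhaustive=True)
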