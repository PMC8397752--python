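"""Boolean machinery for the service model.

A service over S species factorises as ``E = E* ∘ OR^N``: a species
configuration (presence/absence vector) maps to a trait configuration —
trait n present while at least one of its S_n providers survives (a
partial OR) — and an auxiliary Boolean function E* over the N trait
configurations decides whether the service is supplied.  The default E*
is AND (the least redundant choice: the service needs every trait);
arbitrary truth tables are supported so AND can be compared against a
random draw over all 2^(2^N) Boolean functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import SpeciesTraitNetwork

__all__ = [
    "BooleanService",
    "and_service",
    "random_boolean_service",
    "traits_from_species",
    "evaluate_service",
]

AND = "AND"
TRUTH_TABLE = "TRUTH_TABLE"

#: largest N for which an explicit 2^N truth table is allowed
MAX_TABLE_TRAITS = 20


@dataclass(frozen=True)
class BooleanService:
    """The auxiliary function E* over trait configurations.

    ``kind`` is "AND" (service present iff every trait present) or
    "TRUTH_TABLE" (explicit table of length 2^n_traits, indexed by the
    trait configuration read as an integer with trait 0 as the least
    significant bit).
    """

    kind: str
    n_traits: int
    table: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in (AND, TRUTH_TABLE):
            raise ValueError(f"unknown service kind {self.kind!r}")
        if self.n_traits < 1:
            raise ValueError("n_traits must be >= 1")
        if self.kind == TRUTH_TABLE:
            if self.table is None:
                raise ValueError("TRUTH_TABLE service requires a table")
            tab = np.asarray(self.table, dtype=np.uint8)
            if tab.shape != (2**self.n_traits,):
                raise ValueError(
                    f"table must have length 2^{self.n_traits}, got {tab.shape}"
                )
            if not np.isin(tab, (0, 1)).all():
                raise ValueError("table entries must be 0 or 1")
            tab.setflags(write=False)
            object.__setattr__(self, "table", tab)
        elif self.table is not None:
            raise ValueError("AND service takes no table")


def and_service(n_traits: int) -> BooleanService:
    """The AND service: supplied only while all ``n_traits`` traits are present."""
    return BooleanService(kind=AND, n_traits=n_traits)


def random_boolean_service(
    n_traits: int, seed: int | np.random.Generator | None = None
) -> BooleanService:
    """Draw E* uniformly from all 2^(2^N) Boolean functions of N traits.

    Each of the 2^N truth-table outputs is an independent fair coin
    flip.  Reproducible for a fixed seed.  N is capped at
    ``MAX_TABLE_TRAITS`` (the table has 2^N entries).
    """
    if n_traits > MAX_TABLE_TRAITS:
        raise ValueError(
            f"n_traits={n_traits} too large for an explicit truth table "
            f"(max {MAX_TABLE_TRAITS})"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    table = rng.integers(0, 2, size=2**n_traits, dtype=np.uint8)
    return BooleanService(kind=TRUTH_TABLE, n_traits=n_traits, table=table)


def traits_from_species(
    net: SpeciesTraitNetwork, species_presence: np.ndarray
) -> np.ndarray:
    """Map a species configuration to a trait configuration (OR^N).

    Trait n is present (1) iff at least one present species links to it.
    """
    presence = np.asarray(species_presence)
    if presence.shape != (net.n_species,):
        raise ValueError(
            f"species configuration has shape {presence.shape}, "
            f"expected ({net.n_species},)"
        )
    present_rows = net.incidence[presence.astype(bool), :]
    return (present_rows.sum(axis=0) > 0).astype(np.uint8)


def _table_index(trait_presence: np.ndarray) -> int:
    # trait 0 is the least significant bit
    bits = np.asarray(trait_presence, dtype=np.uint64)
    return int((bits << np.arange(bits.size, dtype=np.uint64)).sum())


def evaluate_service(service: BooleanService, trait_presence: np.ndarray) -> int:
    """Evaluate E* on a trait configuration; returns 0 or 1."""
    tc = np.asarray(trait_presence)
    if tc.shape != (service.n_traits,):
        raise ValueError(
            f"trait configuration has shape {tc.shape}, "
            f"expected ({service.n_traits},)"
        )
    if service.kind == AND:
        return int(tc.all())
    return int(service.table[_table_index(tc)])
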