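import itertools

import numpy as np
import pytest

from fragnet import (
    BooleanService,
    RobustnessDistribution,
    ServiceAlreadyLostError,
    SpeciesTraitNetwork,
    and_service,
    enumerate_robustness,
    percentile,
    random_bipartite,
    robustness_of_sequence,
    simulate_robustness,
)


class TestSequenceRobustness:
    def test_full_redundancy_tolerates_all_but_last(self):
        # single trait shared by everyone: loss only at the final removal
        net = SpeciesTraitNetwork.from_matrix(np.ones((5, 1), dtype=int))
        for order in ([0, 1, 2, 3, 4], [4, 3, 2, 1, 0], [2, 0, 4, 1, 3]):
            assert robustness_of_sequence(net, and_service(1), order) == 1.0

    def test_no_redundancy_fails_at_first_removal(self, identity3):
        for order in itertools.permutations(range(3)):
            assert robustness_of_sequence(identity3, and_service(3), order) == pytest.approx(1 / 3)

    def test_hand_traced_orders(self, four_species_net):
        svc = and_service(2)
        # removing the sole provider of B first kills the service at once
        assert robustness_of_sequence(four_species_net, svc, [3, 0, 1, 2]) == 0.25
        # exhausting A's three providers loses the service at step 3
        assert robustness_of_sequence(four_species_net, svc, [0, 1, 2, 3]) == 0.75

    def test_service_lost_at_full_community_is_an_error(self):
        net = SpeciesTraitNetwork.from_matrix([[1, 0], [1, 0]])  # empty trait
        with pytest.raises(ServiceAlreadyLostError):
            robustness_of_sequence(net, and_service(2), [0, 1])

    def test_non_permutation_rejected(self, identity3):
        with pytest.raises(ValueError):
            robustness_of_sequence(identity3, and_service(3), [0, 0, 1])

    def test_truth_table_first_zero_counts(self):
        # non-monotone E*: 0 on (A=1, B=0) but 1 again on (0, 0);
        # the FIRST zero must be used
        net = SpeciesTraitNetwork.from_matrix([[1, 0], [1, 1], [0, 1]])
        table = [1, 0, 1, 1]  # index bit0=trait A, bit1=trait B
        svc = BooleanService("TRUTH_TABLE", 2, table=table)
        # order removing B's providers first: B lost at step 2 -> R = 2/3
        assert robustness_of_sequence(net, svc, [2, 1, 0]) == pytest.approx(2 / 3)


class TestEnumerate:
    def test_worked_example_median_and_histogram(self, worked_example):
        dist = enumerate_robustness(worked_example, and_service(2))
        assert dist.is_exhaustive and dist.n_sequences == 120
        counts = dict(zip(*np.unique(dist.values, return_counts=True)))
        assert counts == {0.6: 24, 0.8: 72, 1.0: 24}
        assert dist.median == 0.8

    def test_two_fully_redundant_species(self):
        net = SpeciesTraitNetwork.from_matrix([[1], [1]])
        dist = enumerate_robustness(net, and_service(1))
        assert dist.values.tolist() == [1.0, 1.0]

    def test_enumeration_bound_enforced(self):
        net = SpeciesTraitNetwork.from_matrix(np.ones((10, 1), dtype=int))
        with pytest.raises(ValueError):
            enumerate_robustness(net, and_service(1))

    def test_matches_large_monte_carlo(self):
        """Exhaustive distribution ≈ 200k Monte-Carlo draws (TV ≤ 0.01)."""
        net = random_bipartite(7, 3, 0.4, seed=99, require_no_empty_trait=True)
        svc = and_service(3)
        ex = enumerate_robustness(net, svc)
        mc = simulate_robustness(net, svc, 200_000, seed=1)
        support = np.arange(1, 8) / 7
        tv = 0.5 * sum(
            abs(np.mean(ex.values == v) - np.mean(mc.values == v))
            for v in support
        )
        assert tv <= 0.01


class TestSimulate:
    def test_seed_reproducibility(self, worked_example):
        svc = and_service(2)
        d1 = simulate_robustness(worked_example, svc, 1000, seed=3)
        d2 = simulate_robustness(worked_example, svc, 1000, seed=3)
        assert np.array_equal(d1.values, d2.values)

    def test_identity_network_constant(self, identity3):
        d = simulate_robustness(identity3, and_service(3), 50, seed=0)
        assert np.all(d.values == pytest.approx(1 / 3))

    def test_bad_reps(self, identity3):
        with pytest.raises(ValueError):
            simulate_robustness(identity3, and_service(3), 0, seed=0)

    def test_support_bounds(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            S = int(rng.integers(2, 15))
            net = random_bipartite(S, 3, 0.5, seed=rng, require_no_empty_trait=True)
            d = simulate_robustness(net, and_service(3), 200, seed=rng)
            assert d.values.min() >= 1 / S - 1e-12
            assert d.values.max() <= 1.0 + 1e-12
            # every value sits on the discrete support m/S
            assert np.allclose(np.round(d.values * S), d.values * S)


class TestPercentile:
    def test_lower_quantile_convention(self):
        dist = RobustnessDistribution(S=5, values=[0.2, 0.4, 0.6, 0.8, 1.0])
        assert percentile(dist, 0.5) == 0.6

    def test_constant_distribution(self):
        dist = RobustnessDistribution(S=4, values=[0.25] * 10)
        for c in (0.1, 0.5, 0.9):
            assert percentile(dist, c) == 0.25

    def test_monotone_in_c(self, worked_example):
        dist = enumerate_robustness(worked_example, and_service(2))
        levels = np.linspace(0.05, 0.95, 19)
        vals = [percentile(dist, c) for c in levels]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_bad_levels(self, worked_example):
        dist = enumerate_robustness(worked_example, and_service(2))
        for c in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                percentile(dist, c)


def test_adding_links_stochastically_increases_robustness():
    """Extra redundancy can only shift the robustness distribution up."""
    rng = np.random.default_rng(13)
    for _ in range(10):
        net = random_bipartite(6, 3, 0.4, seed=rng, require_no_empty_trait=True)
        zeros = np.argwhere(net.incidence == 0)
        if zeros.size == 0:
            continue
        i, j = zeros[rng.integers(len(zeros))]
        richer_inc = np.array(net.incidence)
        richer_inc[i, j] = 1
        richer = SpeciesTraitNetwork.from_matrix(richer_inc)
        base = enumerate_robustness(net, and_service(3)).values
        more = enumerate_robustness(richer, and_service(3)).values
        # first-order stochastic dominance over the common support
        for v in np.arange(1, 7) / 6:
            assert np.mean(more <= v - 1e-12) <= np.mean(base <= v - 1e-12) + 1e-12


def test_distribution_export(worked_example):
    dist = enumerate_robustness(worked_example, and_service(2))
    df = dist.to_frame()
    assert list(df.columns) == ["robustness", "count"]
    assert df["count"].sum() == 120
    payload = dist.percentiles_json((0.5,))
    assert '"0.5": 0.8' in payload
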