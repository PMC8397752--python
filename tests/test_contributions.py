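import numpy as np
import pytest
from scipy import stats

from fragnet import (
    SpeciesTraitNetwork,
    connectance_after_removal,
    dispersion_controlled,
    random_bipartite,
    rank_species,
    ranking_table,
    remove_species,
    species_contribution,
    summarize,
    variance_after_removal,
)


@pytest.fixture
def worked_case():
    """S=5, N=2, L=8 with one species of degree 2 among otherwise full rows."""
    return SpeciesTraitNetwork.from_matrix(
        [[1, 1], [1, 1], [1, 1], [1, 1], [0, 0]]
    )


@pytest.fixture
def generalist_vs_specialist():
    """10 species x 5 traits: a generalist providing three uncommon traits
    and a specialist sharing one common trait."""
    species = ["generalist", "specialist", "a1", "a2", "a3", "a4", "a5",
               "b1", "b2", "b3"]
    traits = ["common", "u1", "u2", "u3", "u4"]
    inc = np.zeros((10, 5), dtype=int)
    inc[1:7, 0] = 1            # common trait: specialist + a1..a5
    inc[0, 1:4] = 1            # generalist: three uncommon traits
    inc[7, [1, 4]] = 1
    inc[8, [2, 4]] = 1
    inc[9, [3, 4]] = 1
    return SpeciesTraitNetwork(tuple(species), tuple(traits), inc)


class TestConnectanceUpdate:
    def test_worked_case_approximation_gap(self, worked_case):
        s = summarize(worked_case)
        assert (s.S, s.N, s.L) == (5, 2, 8)
        # species 0 has exactly L_i = 2
        assert connectance_after_removal(s, 0) == pytest.approx(0.76)
        exact = summarize(remove_species(worked_case, 0)).p
        assert exact == pytest.approx(0.75)

    def test_average_degree_species_leaves_p_unchanged(self):
        net = SpeciesTraitNetwork.from_matrix(np.ones((4, 3), dtype=int))
        s = summarize(net)
        for i in range(4):  # every L_i/L = 1/S
            assert connectance_after_removal(s, i) == pytest.approx(s.p)

    def test_highest_degree_species_reduces_p_most(self):
        net = random_bipartite(20, 8, 0.3, seed=4)
        s = summarize(net)
        preds = [connectance_after_removal(s, i) for i in range(20)]
        assert int(np.argmin(preds)) == int(np.argmax(s.L_i))

    def test_single_species_rejected(self):
        s = summarize(SpeciesTraitNetwork.from_matrix([[1]]))
        with pytest.raises(ValueError):
            connectance_after_removal(s, 0)


class TestVarianceUpdate:
    def test_average_trait_holder_leaves_variance_unchanged(self):
        net = SpeciesTraitNetwork.from_matrix(np.ones((4, 3), dtype=int))
        for i in range(4):
            assert variance_after_removal(net, i) == pytest.approx(
                summarize(net).var_S_n
            )

    def test_rare_trait_holder_increases_predicted_variance(
        self, generalist_vs_specialist
    ):
        net = generalist_vs_specialist
        s = summarize(net)
        assert variance_after_removal(net, 0) > s.var_S_n  # uncommon traits

    def test_unlinked_species_leaves_variance_unchanged(self):
        net = SpeciesTraitNetwork.from_matrix([[1, 1], [1, 1], [0, 0]])
        assert variance_after_removal(net, 2) == summarize(net).var_S_n

    def test_prediction_gap_is_the_dropped_second_order_term(self):
        """Exact minus predicted variance equals (L_i/N)(1 - L_i/N) exactly."""
        rng = np.random.default_rng(31)
        for _ in range(50):
            S = int(rng.integers(3, 25))
            N = int(rng.integers(2, 12))
            net = random_bipartite(S, N, 0.35, seed=rng)
            s = summarize(net)
            i = int(rng.integers(S))
            exact = summarize(remove_species(net, i)).var_S_n
            pred = variance_after_removal(net, i)
            gap = (s.L_i[i] / N) * (1 - s.L_i[i] / N)
            assert exact - pred == pytest.approx(gap, abs=1e-10)


class TestSpeciesContribution:
    def test_redundant_duplicate_contributes_little(self):
        # species 0 and 1 identical; species 3 holds a unique trait
        net = SpeciesTraitNetwork.from_matrix(
            [[1, 1, 0], [1, 1, 0], [1, 0, 0], [0, 0, 1], [1, 0, 1]]
        )
        dup = species_contribution(net, 0, mode="exact")
        unique = species_contribution(net, 3, mode="exact")
        assert abs(dup.delta_fstar_exact) < abs(unique.delta_fstar_exact)
        assert unique.delta_fstar_exact > 0

    def test_generalist_outranks_specialist(self, generalist_vs_specialist):
        ranked = rank_species(generalist_vs_specialist, mode="exact")
        order = [r.species_id for r in ranked]
        assert order.index("generalist") < order.index("specialist")
        assert ranked[0].species_id == "generalist"

    def test_approx_tracks_exact_on_large_networks(self):
        rng = np.random.default_rng(21)
        for _ in range(3):
            net = dispersion_controlled(100, 30, 0.15, 0.5, seed=rng)
            recs = [species_contribution(net, i, mode="both") for i in range(100)]
            rho = stats.spearmanr(
                [r.delta_fstar_pred for r in recs],
                [r.delta_fstar_exact for r in recs],
            ).statistic
            assert rho > 0.8

    def test_bad_mode(self, identity3):
        with pytest.raises(ValueError):
            species_contribution(identity3, 0, mode="nope")


class TestRanking:
    def test_identity_network_all_tie(self, identity3):
        ranked = rank_species(identity3, mode="exact")
        deltas = {round(r.delta_fstar_exact, 12) for r in ranked}
        assert len(deltas) == 1  # full symmetry
        # deterministic tie-break by label
        assert [r.species_id for r in ranked] == sorted(
            identity3.species_ids, key=str
        )
        assert not ranked[0].corrected  # dispersion zero: plain f_c used

    def test_output_length_and_table(self, generalist_vs_specialist):
        ranked = rank_species(generalist_vs_specialist, mode="approx")
        assert len(ranked) == 10
        df = ranking_table(ranked)
        assert list(df["species_id"]) == [r.species_id for r in ranked]
        assert {"L_i", "delta_fstar_pred"} <= set(df.columns)


def test_remove_and_readd_round_trip(four_species_net):
    """Re-inserting a removed species restores every summary statistic."""
    before = summarize(four_species_net)
    reduced = remove_species(four_species_net, 1)
    restored = SpeciesTraitNetwork(
        reduced.species_ids[:1] + (four_species_net.species_ids[1],)
        + reduced.species_ids[1:],
        reduced.trait_ids,
        np.vstack(
            [
                reduced.incidence[:1],
                four_species_net.incidence[1:2],
                reduced.incidence[1:],
            ]
        ),
    )
    after = summarize(restored)
    assert (after.S, after.N, after.L, after.p) == (
        before.S, before.N, before.L, before.p
    )
    assert after.var_S_n == before.var_S_n
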