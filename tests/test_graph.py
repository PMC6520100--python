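import numpy as np
import pandas as pd
import pytest

import boldfractal as bf
from boldfractal.graph import (
    eigenvector_centrality,
    nodal_efficiency,
    participation_coefficient,
    shortest_path_lengths,
    strength,
    within_module_z,
)
from boldfractal.parcellate import from_labels
from oracles import (
    all_pairs_shortest_paths_bruteforce,
    betweenness_bruteforce,
    eigenvector_power_iteration,
    global_efficiency_bruteforce,
    participation_bruteforce,
    within_module_z_bruteforce,
)


def _connected(W):
    return np.isfinite(shortest_path_lengths(W)).all()


class TestOracleEquivalence:
    """Path-based and module-based measures agree with brute-force
    enumeration on 100 random small graphs to 1e-9."""

    def test_shortest_paths(self, random_small_graphs):
        for W in random_small_graphs:
            np.testing.assert_allclose(
                shortest_path_lengths(W),
                all_pairs_shortest_paths_bruteforce(W),
                atol=1e-9,
            )

    def test_global_efficiency(self, random_small_graphs):
        for W in random_small_graphs:
            assert bf.global_efficiency(W) == pytest.approx(
                global_efficiency_bruteforce(W), abs=1e-9
            )

    def test_nodal_efficiency_sums_to_global(self, random_small_graphs):
        for W in random_small_graphs:
            ne = nodal_efficiency(W)
            assert ne.mean() == pytest.approx(bf.global_efficiency(W), abs=1e-12)
            D = all_pairs_shortest_paths_bruteforce(W)
            inv = np.where(np.isfinite(D) & (D > 0), 1.0 / np.where(D > 0, D, 1), 0.0)
            np.testing.assert_allclose(ne, inv.sum(axis=1) / (W.shape[0] - 1), atol=1e-9)

    def test_betweenness(self, random_small_graphs):
        for W in random_small_graphs:
            np.testing.assert_allclose(
                bf.betweenness(W), betweenness_bruteforce(W), atol=1e-9
            )

    def test_eigenvector(self, random_small_graphs):
        checked = 0
        for W in random_small_graphs:
            if not _connected(W):
                continue  # Perron vector unique only for irreducible graphs
            ours = eigenvector_centrality(W)
            oracle = eigenvector_power_iteration(W)
            np.testing.assert_allclose(ours, np.abs(oracle), atol=1e-8)
            checked += 1
        assert checked >= 50

    def test_module_measures(self, random_small_graphs):
        rng = np.random.default_rng(7)
        for W in random_small_graphs:
            part = rng.integers(0, 2, size=W.shape[0])
            np.testing.assert_allclose(
                participation_coefficient(W, part),
                participation_bruteforce(W, part),
                atol=1e-12,
            )
            np.testing.assert_allclose(
                within_module_z(W, part),
                within_module_z_bruteforce(W, part),
                atol=1e-12,
            )


class TestDeltaEfficiency:
    def test_complete_graph_reduced_is_zero(self):
        W = np.ones((6, 6)) - np.eye(6)
        for node in range(6):
            assert bf.delta_efficiency(W, node) == pytest.approx(0.0, abs=1e-12)

    def test_path_graph_middle_node_disconnects(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = W[1, 2] = W[2, 1] = 1.0
        assert bf.delta_efficiency(W, 1) == pytest.approx(-100.0)

    def test_isolate_convention_complete_graph(self):
        n = 4
        W = np.ones((n, n)) - np.eye(n)
        # isolating one node zeroes its 2(n-1) ordered pairs out of n(n-1)
        expected = 100.0 * ((n - 2) / n - 1.0)
        assert bf.delta_efficiency(W, 0, lesion_convention="isolate") == pytest.approx(
            expected
        )

    def test_leaf_removal_can_increase_efficiency(self):
        # a weakly attached leaf drags the pair-average down; removing it helps
        W = np.ones((4, 4)) - np.eye(4)
        W[3, :] = W[:, 3] = 0.0
        W[3, 0] = W[0, 3] = 0.01
        assert bf.delta_efficiency(W, 3) > 0

    def test_unknown_convention_rejected(self):
        W = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError):
            bf.delta_efficiency(W, 0, lesion_convention="typo")

    def test_zero_graph_yields_nan_with_warning(self):
        with pytest.warns(UserWarning, match="efficiency is 0"):
            assert np.isnan(bf.delta_efficiency(np.zeros((3, 3)), 0))


class TestInputValidation:
    def test_negative_weights_rejected(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = -1.0
        with pytest.raises(ValueError, match="negative"):
            bf.global_efficiency(W)

    def test_asymmetric_rejected(self):
        W = np.zeros((3, 3))
        W[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            bf.global_efficiency(W)

    def test_nonsquare_rejected(self):
        with pytest.raises(ValueError):
            bf.global_efficiency(np.zeros((3, 4)))

    def test_strength_matches_row_sums(self, random_small_graphs):
        W = random_small_graphs[0]
        np.testing.assert_allclose(strength(W), W.sum(axis=1))


class TestDetectModules:
    def test_recovers_planted_partition(self):
        W, labels = bf.simulate_modular_network(
            bf.ModularNetSpec(n_nodes=40, n_modules=4, p_within_weight=2.0,
                              p_between_weight=0.05, seed=5)
        )
        found = bf.detect_modules(W, seed=0)
        same_true = labels[:, None] == labels[None, :]
        same_found = found[:, None] == found[None, :]
        agreement = (same_true == same_found).mean()
        assert agreement >= 0.95

    def test_seed_determinism(self):
        W, _ = bf.simulate_modular_network(bf.ModularNetSpec(seed=3))
        np.testing.assert_array_equal(
            bf.detect_modules(W, seed=4), bf.detect_modules(W, seed=4)
        )


class TestNodeCentralities:
    def test_columns_and_zscores(self):
        W, labels = bf.simulate_modular_network(bf.ModularNetSpec(seed=6))
        table = bf.node_centralities(W, partition=labels)
        for col in bf.BASE_METRICS:
            assert col in table.columns and col + "_z" in table.columns
            z = table[col + "_z"].to_numpy()
            if np.nanstd(table[col].to_numpy()) > 0:
                assert np.nanmean(z) == pytest.approx(0.0, abs=1e-10)
                assert np.nanstd(z) == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_array_equal(table.attrs["partition"], labels)

    def test_partition_derived_when_missing(self):
        W, _ = bf.simulate_modular_network(bf.ModularNetSpec(seed=8))
        table = bf.node_centralities(W, partition_seed=1)
        assert table.attrs["partition"].shape == (W.shape[0],)

    def test_parcel_ids_carried(self):
        W = np.ones((4, 4)) - np.eye(4)
        ids = np.array([11, 12, 21, 22])
        table = bf.node_centralities(W, parcel_ids=ids)
        np.testing.assert_array_equal(table["id"], ids)

    def test_bad_partition_length_rejected(self):
        W = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError):
            bf.node_centralities(W, partition=np.zeros(3, dtype=int))


class TestHomologueRatio:
    def _two_pair_parcellation(self):
        labels = np.zeros((4, 1, 1), int)
        for i in range(4):
            labels[i, 0, 0] = i + 1
        aff = np.eye(4)
        aff[0, 3] = -1.5  # parcels 1,2 left of x=0; 3,4 right
        parc = from_labels(labels, aff)
        parc.table["homologue_id"] = [4, 3, 2, 1]
        return parc

    def test_ratios_computed_against_homologue(self):
        parc = self._two_pair_parcellation()
        metrics = pd.DataFrame({"id": [1, 2, 3, 4], "strength": [2.0, 3.0, 6.0, 8.0]})
        out = bf.homologue_ratio(metrics, parc, columns=("strength",))
        np.testing.assert_allclose(
            out["strength_ratio"], [2.0 / 8.0, 3.0 / 6.0, 2.0, 4.0]
        )

    def test_missing_homologue_gives_nan(self):
        parc = self._two_pair_parcellation()
        metrics = pd.DataFrame({"id": [1, 2, 3], "strength": [2.0, 3.0, 6.0]})
        out = bf.homologue_ratio(metrics, parc, columns=("strength",))
        assert np.isnan(out.loc[out["id"] == 1, "strength_ratio"]).all()
        assert out.loc[out["id"] == 2, "strength_ratio"].iloc[0] == pytest.approx(0.5)

    def test_unpaired_and_zero_denominator_nan(self):
        parc = self._two_pair_parcellation()
        parc.table.loc[parc.table["id"] == 1, "homologue_id"] = -1
        parc.table.loc[parc.table["id"] == 4, "homologue_id"] = -1
        metrics = pd.DataFrame({"id": [1, 2, 3, 4], "strength": [2.0, 3.0, 0.0, 8.0]})
        out = bf.homologue_ratio(metrics, parc, columns=("strength",)).set_index("id")
        assert np.isnan(out.loc[1, "strength_ratio"])  # unpaired
        assert np.isnan(out.loc[2, "strength_ratio"])  # denominator 0
        assert out.loc[3, "strength_ratio"] == pytest.approx(0.0)
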