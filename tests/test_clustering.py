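import numpy as np
import pandas as pd
import pytest

from macroindex.clustering import (
    assign_macro_groups,
    compute_pac,
    consensus_cluster,
    filter_fraction_matrix,
    pam,
    pearson_distance,
    select_core_samples,
    select_k,
    silhouette_widths,
)
from macroindex.io import ClinicalTable


class TestFilterFractionMatrix:
    def _matrix(self, zero_counts, n_samples=10):
        rows = []
        for z in zero_counts:
            row = np.linspace(0.1, 0.9, n_samples)
            row[:z] = 0.0
            rows.append(row)
        return pd.DataFrame(rows, index=[f"t{i}" for i in range(len(zero_counts))],
                            columns=[f"s{j}" for j in range(n_samples)])

    def test_cell_type_zero_in_over_half_dropped(self):
        out = filter_fraction_matrix(self._matrix([6, 0]))
        assert list(out.index) == ["t1"]

    def test_exactly_half_kept(self):
        out = filter_fraction_matrix(self._matrix([5, 0]))
        assert list(out.index) == ["t0", "t1"]

    def test_high_pvalue_samples_dropped_then_zero_rule(self):
        """Surviving set matches hand enumeration of both rules on a toy."""
        rng = np.random.default_rng(5)
        n, types = 20, 5
        fr = pd.DataFrame(rng.uniform(0.01, 0.5, size=(types, n)),
                          index=[f"t{i}" for i in range(types)],
                          columns=[f"s{j}" for j in range(n)])
        zero_mask = rng.random((types, n)) < 0.4
        fr = fr.mask(pd.DataFrame(zero_mask, index=fr.index, columns=fr.columns), 0.0)
        pvals = pd.Series(rng.uniform(0, 0.1, size=n), index=fr.columns)
        out = filter_fraction_matrix(fr, pvals)
        keep_samples = [s for s in fr.columns if pvals[s] <= 0.05]
        keep_types = [
            t for t in fr.index
            if (fr.loc[t, keep_samples] == 0).sum() <= len(keep_samples) / 2
        ]
        assert list(out.columns) == keep_samples
        assert list(out.index) == keep_types

    def test_all_types_removed_errors(self):
        with pytest.raises(ValueError, match="all cell types"):
            filter_fraction_matrix(self._matrix([9, 9]))


def _two_archetype_profiles(n_per=20, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal([5, 1, 1, 1], 0.2, size=(n_per, 4))
    b = rng.normal([1, 1, 5, 1], 0.2, size=(n_per, 4))
    X = pd.DataFrame(np.vstack([a, b]),
                     index=[f"s{i:02d}" for i in range(2 * n_per)])
    labels = np.array([0] * n_per + [1] * n_per)
    return X, labels


class TestConsensusCluster:
    def test_separated_archetypes_give_crisp_consensus(self):
        X, truth = _two_archetype_profiles()
        res = consensus_cluster(X, k_range=[2], n_resample=50, seed=0)
        M = res.consensus[2].to_numpy()
        off = M[np.triu_indices_from(M, k=1)]
        assert np.all((off < 0.05) | (off > 0.95))
        assign = res.assignments[2].to_numpy()
        # misassignment rate 0 up to label permutation
        assert min((assign != truth).mean(), (assign == truth).mean()) == 0.0

    def test_single_full_resample_is_block_binary(self):
        X, _ = _two_archetype_profiles(n_per=6)
        res = consensus_cluster(X, k_range=[2], n_resample=1, subsample_frac=1.0, seed=1)
        M = res.consensus[2].to_numpy()
        assert set(np.unique(M)) <= {0.0, 1.0}

    def test_constant_profile_rejected(self):
        X = pd.DataFrame([[1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4], [4, 3, 2, 1],
                          [1, 3, 2, 4], [2, 1, 4, 3]])
        with pytest.raises(ValueError, match="constant profile"):
            consensus_cluster(X, k_range=[2], n_resample=5, seed=0)

    def test_consensus_invariant_to_affine_feature_scaling(self):
        """Pearson distance is affine-invariant per sample profile."""
        X, _ = _two_archetype_profiles(n_per=8, seed=3)
        res1 = consensus_cluster(X, k_range=[2], n_resample=20, seed=5)
        res2 = consensus_cluster(X * 3.0 + 7.0, k_range=[2], n_resample=20, seed=5)
        pd.testing.assert_frame_equal(res1.consensus[2], res2.consensus[2])


class TestPac:
    def test_perfect_block_matrix_has_zero_pac(self):
        M = np.kron(np.eye(2), np.ones((3, 3)))
        assert compute_pac(M) == 0.0

    def test_all_ambiguous_has_pac_one(self):
        M = np.full((4, 4), 0.5)
        np.fill_diagonal(M, 1.0)
        assert compute_pac(M) == 1.0

    def test_matches_direct_count_on_random_matrix(self, rng):
        A = rng.uniform(size=(6, 6))
        M = (A + A.T) / 2
        np.fill_diagonal(M, 1.0)
        expected = np.mean([
            1 if 0.1 < M[i, j] < 0.9 else 0
            for i in range(6) for j in range(i + 1, 6)
        ])
        assert compute_pac(M) == pytest.approx(expected)

    def test_monotone_under_added_noise(self, rng):
        """PAC never decreases as uniform noise pushes entries inward."""
        M = np.kron(np.eye(2), np.ones((5, 5)))
        pacs = []
        for eps in (0.0, 0.1, 0.2, 0.3, 0.45):
            noisy = np.clip(M * (1 - 2 * eps) + eps, 0, 1)
            np.fill_diagonal(noisy, 1.0)
            pacs.append(compute_pac(noisy))
        assert all(b >= a for a, b in zip(pacs, pacs[1:]))

    def test_asymmetric_rejected(self):
        M = np.array([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            compute_pac(M)


class TestSelectK:
    @pytest.mark.parametrize(
        "pac, expected",
        [({2: 0.05, 3: 0.2}, 2), ({2: 0.1, 3: 0.1}, 2), ({4: 0.3, 3: 0.1, 2: 0.2}, 3)],
    )
    def test_minimal_pac_with_smallest_k_tiebreak(self, pac, expected):
        assert select_k(pac) == expected


class TestSilhouette:
    def test_two_tight_far_pairs(self):
        D = np.array([
            [0.0, 0.1, 5.0, 5.0],
            [0.1, 0.0, 5.0, 5.0],
            [5.0, 5.0, 0.0, 0.1],
            [5.0, 5.0, 0.1, 0.0],
        ])
        s = silhouette_widths(D, pd.Series([0, 0, 1, 1]))
        assert (s > 0.9).all()

    def test_equidistant_point_is_zero(self):
        D = np.array([
            [0.0, 1.0, 1.0],
            [1.0, 0.0, 1.0],
            [1.0, 1.0, 0.0],
        ])
        s = silhouette_widths(D, pd.Series([0, 0, 1]))
        assert s.iloc[0] == pytest.approx(0.0)

    def test_matches_brute_force_formula(self, rng):
        A = rng.uniform(0.1, 2.0, size=(8, 8))
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0.0)
        labels = pd.Series([0, 0, 0, 1, 1, 2, 2, 2])
        s = silhouette_widths(D, labels)
        for i in range(8):
            own = labels[i]
            mine = [j for j in range(8) if labels[j] == own and j != i]
            a = np.mean([D[i, j] for j in mine])
            b = min(
                np.mean([D[i, j] for j in range(8) if labels[j] == other])
                for other in (0, 1, 2) if other != own
            )
            assert s.iloc[i] == pytest.approx((b - a) / max(a, b))

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="2 clusters"):
            silhouette_widths(np.zeros((3, 3)), pd.Series([0, 0, 0]))


class TestCoreSamples:
    def test_cluster_of_four_keeps_three(self):
        s = pd.Series([0.9, 0.8, 0.7, 0.6], index=list("abcd"))
        flags = select_core_samples(s, pd.Series([0] * 4, index=list("abcd")))
        assert flags.sum() == 3
        assert not flags["d"]

    def test_singleton_cluster_kept(self):
        s = pd.Series([0.5, 0.9, 0.8], index=list("abc"))
        flags = select_core_samples(s, pd.Series([0, 1, 1], index=list("abc")))
        assert flags["a"]

    def test_tied_widths_deterministic(self):
        ids = [f"s{i}" for i in range(8)]
        s = pd.Series([0.5] * 8, index=ids)
        flags = select_core_samples(s, pd.Series([0] * 8, index=ids))
        assert flags.sum() == 6
        assert list(flags[flags].index) == ids[:6]  # id-order tie-break


class TestAssignMacroGroups:
    def _toy(self):
        ids = list("abcdef")
        assignments = pd.Series([0, 0, 0, 0, 0, 1], index=ids)
        core = pd.Series(True, index=ids)
        clin = ClinicalTable(pd.DataFrame({
            "sample_id": ids,
            "histology": ["Glioblastoma"] * 3 + ["Astrocytoma"] * 3,
        }))
        m2 = pd.Series([0.5, 0.5, 0.5, 0.4, 0.4, 0.05], index=ids)
        return assignments, core, clin, m2

    def test_toy_crossing(self):
        assignments, core, clin, m2 = self._toy()
        groups = assign_macro_groups(assignments, core, clin, m2)
        assert (groups.labels[list("abc")] == "Macro1").all()
        assert (groups.labels[list("de")] == "Macro2").all()
        assert groups.labels["f"] == "Macro3"
        assert groups.cluster1_id == 0

    def test_identical_mean_m2_undecidable(self):
        assignments, core, clin, _ = self._toy()
        m2 = pd.Series(0.3, index=assignments.index)
        with pytest.raises(ValueError, match="identical mean"):
            assign_macro_groups(assignments, core, clin, m2)

    def test_requires_two_clusters(self):
        assignments, core, clin, m2 = self._toy()
        with pytest.raises(ValueError, match="2 clusters"):
            assign_macro_groups(pd.Series(0, index=assignments.index), core, clin, m2)

    def test_non_core_samples_unlabeled(self):
        assignments, core, clin, m2 = self._toy()
        core["a"] = False
        groups = assign_macro_groups(assignments, core, clin, m2)
        assert "a" not in groups.labels.index


class TestPam:
    def test_recovers_separated_blocks(self):
        X, truth = _two_archetype_profiles(n_per=10, seed=2)
        D = pearson_distance(X.to_numpy())
        labels = pam(D, 2)
        assert min((labels != truth).mean(), (labels == truth).mean()) == 0.0
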