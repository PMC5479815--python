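import itertools

import numpy as np
import pytest
from sklearn.cluster import KMeans

import tastecourse as tc
from tastecourse.cluster import lloyd
from .conftest import make_matrix


def brute_force_min_wss(data, k):
    """Global minimum within-cluster SS by enumerating all assignments."""
    n = data.shape[0]
    best = np.inf
    best_assign = None
    for assign in itertools.product(range(k), repeat=n):
        assign = np.array(assign)
        wss = 0.0
        for c in range(k):
            pts = data[assign == c]
            if len(pts):
                wss += ((pts - pts.mean(axis=0)) ** 2).sum()
        if wss < best - 1e-12:
            best, best_assign = wss, assign
    return best, best_assign


def _normalized(data):
    stages = [f"d{2 * (i + 1)}" for i in range(data.shape[1])]
    return make_matrix(data, kind="normalized", stages=stages)


class TestKmeans:
    def test_k1_degenerate(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(10, 4))
        model = tc.kmeans_cluster(_normalized(data), k=1, seed=0)
        np.testing.assert_allclose(model.centers[0], data.mean(axis=0))
        assert model.within_ss == pytest.approx(
            ((data - data.mean(axis=0)) ** 2).sum())

    def test_two_separated_groups_equal_exhaustive_bipartition(self):
        rng = np.random.default_rng(1)
        data = np.vstack([rng.normal(0, 0.1, (3, 3)),
                          rng.normal(5, 0.1, (3, 3))])
        model = tc.kmeans_cluster(_normalized(data), k=2, n_starts=20, seed=3)
        best, assign = brute_force_min_wss(data, 2)
        assert model.within_ss == pytest.approx(best)
        groups = {frozenset(np.flatnonzero(assign == c)) for c in range(2)}
        ours = {frozenset(np.flatnonzero(model.assignments.to_numpy() == c))
                for c in (1, 2)}
        assert groups == ours

    @pytest.mark.parametrize("n,k,seed", [(5, 2, 0), (6, 2, 1), (7, 3, 2),
                                          (8, 3, 3), (8, 2, 4)])
    def test_matches_exhaustive_search_on_tiny_instances(self, n, k, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(n, 3))
        model = tc.kmeans_cluster(_normalized(data), k=k, n_starts=64, seed=7)
        best, _ = brute_force_min_wss(data, k)
        assert model.within_ss == pytest.approx(best, abs=1e-9)

    def test_defaults_recorded(self, default_dataset):
        a, _, _, _ = default_dataset
        norm = tc.log_normalize(tc.compute_rpkm(a).subset(a.gene_ids[:50]))
        model = tc.kmeans_cluster(norm, seed=5)
        assert (model.k, model.n_starts, model.max_iter) == (4, 30, 30000)
        assert model.seed == 5

    def test_within_ss_nonincreasing_in_n_starts(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(60, 5))
        sm = _normalized(data)
        wss = [tc.kmeans_cluster(sm, k=4, n_starts=s, seed=11).within_ss
               for s in (1, 5, 15, 30)]
        assert all(a >= b - 1e-12 for a, b in zip(wss, wss[1:]))

    def test_centers_are_means_of_assigned_profiles(self, default_dataset):
        a, _, _, _ = default_dataset
        norm = tc.log_normalize(tc.compute_rpkm(a))
        model = tc.kmeans_cluster(norm, seed=0)
        data = norm.values.to_numpy()
        for c in range(1, 5):
            mask = (model.assignments == c).to_numpy()
            np.testing.assert_allclose(model.centers[c - 1],
                                       data[mask].mean(axis=0), atol=1e-6)

    def test_matches_sklearn_on_separated_data(self):
        rng = np.random.default_rng(3)
        centers = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4]], float)
        data = np.vstack([c + rng.normal(0, 0.2, (40, 3)) for c in centers])
        model = tc.kmeans_cluster(_normalized(data), k=4, n_starts=20, seed=1)
        sk = KMeans(n_clusters=4, n_init=20, random_state=0).fit(data)
        assert model.within_ss == pytest.approx(sk.inertia_, rel=1e-9)

    def test_permuting_genes_permutes_assignments(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(30, 4))
        init = data[[0, 10, 20]]
        assign, _, wss = lloyd(data, init)
        perm = rng.permutation(30)
        assign_p, _, wss_p = lloyd(data[perm], init)
        assert wss == pytest.approx(wss_p)
        assert (assign[perm] == assign_p).all()

    def test_input_validation(self):
        sm = _normalized(np.zeros((3, 4)))
        with pytest.raises(tc.InputError):
            tc.kmeans_cluster(sm, k=5)
        bad = _normalized(np.zeros((3, 4)))
        bad.values.iloc[0, 0] = np.nan
        with pytest.raises(tc.InputError):
            tc.kmeans_cluster(bad, k=2)


class TestLabelArchetypes:
    def _model_with_centers(self, centers):
        import pandas as pd

        k = centers.shape[0]
        return tc.ClusterModel(
            k=k,
            assignments=__import__("pandas").Series(
                np.arange(k) + 1, index=[f"g{i}" for i in range(k)]),
            centers=centers.astype(float),
            within_ss=0.0,
            stages=[f"d{d}" for d in (2, 4, 6, 8, 10, 12, 14)],
            seed=0, n_starts=1, max_iter=1,
        )

    def test_recovers_template_permutation(self):
        templates = tc.default_archetypes()
        centered = np.stack([t.template_array - t.template_array.mean()
                             for t in templates])
        perm = [2, 0, 3, 1]
        model = self._model_with_centers(centered[perm])
        tc.label_archetypes(model, templates)
        expected = {i + 1: templates[p].name for i, p in enumerate(perm)}
        assert model.archetype_labels == expected

    def test_stable_under_small_noise_vs_enumeration(self):
        rng = np.random.default_rng(5)
        templates = tc.default_archetypes()
        centered = np.stack([t.template_array - t.template_array.mean()
                             for t in templates])
        perm = [3, 1, 0, 2]
        noisy = centered[perm] + rng.normal(0, 0.02, centered.shape)
        model = self._model_with_centers(noisy)
        tc.label_archetypes(model, templates)
        assert model.archetype_labels == {i + 1: templates[p].name
                                          for i, p in enumerate(perm)}

    def test_flat_center_matches_flat_template_despite_zero_variance(self):
        templates = tc.default_archetypes()
        centered = np.stack([t.template_array - t.template_array.mean()
                             for t in templates])
        model = self._model_with_centers(centered)  # row 3 is all-zero (flat)
        tc.label_archetypes(model, templates)
        assert model.archetype_labels[3] == "flat"

    def test_template_count_mismatch_rejected(self):
        templates = tc.default_archetypes()
        model = self._model_with_centers(np.zeros((2, 7)))
        with pytest.raises(tc.InputError):
            tc.label_archetypes(model, templates)


class TestStageDendrogram:
    def test_first_merge_is_closest_pair(self):
        # columns at pairwise distances (1, 5, ~5): d2-d4 merge first
        vals = np.array([[0.0, 1.0, 5.0]] * 4)
        sm = make_matrix(vals, kind="log_rpkm", stages=["d2", "d4", "d6"])
        dend = tc.cluster_stages(sm)
        early, late = tc.two_branch_split(dend)
        assert early == {"d2", "d4"} and late == {"d6"}

    def test_identical_columns_merge_at_height_zero(self):
        vals = np.ones((5, 4))
        sm = make_matrix(vals, kind="log_rpkm")
        dend = tc.cluster_stages(sm)
        np.testing.assert_allclose(dend.heights, 0.0)

    def test_heights_nondecreasing(self, default_dataset):
        a, _, _, _ = default_dataset
        dend = tc.cluster_stages(tc.log_transform(tc.compute_rpkm(a)))
        assert (np.diff(dend.heights) >= -1e-12).all()
        assert len(dend.heights) == 6  # n_stages - 1 merges

    def test_newick_contains_all_stages(self, default_dataset):
        a, _, _, _ = default_dataset
        dend = tc.cluster_stages(tc.log_transform(tc.compute_rpkm(a)))
        nwk = dend.to_newick()
        assert nwk.endswith(";")
        for s in a.stages:
            assert s in nwk

    def test_single_stage_rejected(self):
        with pytest.raises(tc.InputError):
            make_matrix(np.ones((3, 1)), stages=["d2"])
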