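"""Screening, clustering and treatment-reversal selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

import phostrend as pt
from phostrend.cluster import _standardize_rows, fuzzy_cmeans
from phostrend.matrix import ConfigurationError, GROUPS
from tests.conftest import make_matrix


def _jitter(vals, scale=1e-3, seed=0):
    rng = np.random.default_rng(seed)
    return [v * (1 + scale * rng.standard_normal()) for v in vals]


class TestAnovaScreen:
    def test_equal_group_means_fail(self):
        res = pt.anova_screen(make_matrix({"f1": [2.0] * 8}), alpha=0.05)
        assert res.table.loc["f1", "p"] == 1.0
        assert not res.table.loc["f1", "passed"]

    def test_strong_group_effect_passes(self):
        res = pt.anova_screen(
            make_matrix({"f1": _jitter([1, 1, 1, 1, 4, 4, 1, 1])}), alpha=0.05
        )
        assert res.table.loc["f1", "p"] < 1e-4
        assert res.table.loc["f1", "passed"]

    def test_alpha_one_passes_everything(self):
        mat = make_matrix({"f1": [2.0] * 8, "f2": _jitter([1, 1, 2, 2, 4, 4, 1, 1])})
        res = pt.anova_screen(mat, alpha=1.0)
        assert res.table["passed"].all()

    def test_matches_closed_form_f(self):
        """F agrees with the sums-of-squares formula on a hand-set example."""
        vals = [1.0, 1.2, 0.9, 1.1, 2.0, 2.2, 1.0, 0.8]
        res = pt.anova_screen(make_matrix({"f1": vals}))
        logv = np.log2(vals)
        groups = [logv[i : i + 2] for i in range(0, 8, 2)]
        grand = logv.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        F = (ss_between / 3) / (ss_within / 4)
        assert res.table.loc["f1", "F"] == pytest.approx(F, rel=1e-9)


class TestKMeans:
    def test_antipodal_templates_separate(self, noise_free_config):
        mat, truth = pt.simulate_proteome(noise_free_config)
        rel = pt.relative_quantify(mat)
        planted = truth.protein_template[truth.protein_template >= 0]
        labels = pt.kmeans_clusters(rel.subset(planted.index), k=2, seed=1)
        # exact partition match (up to label swap)
        tab = pd.crosstab(planted, labels)
        assert (tab.to_numpy() > 0).sum() == 2

    def test_k_one_single_cluster(self, default_dataset):
        rel = pt.relative_quantify(default_dataset.proteome)
        labels = pt.kmeans_clusters(rel, k=1, seed=0)
        assert set(labels) == {0}

    def test_k_larger_than_features_rejected(self):
        mat = make_matrix({"f1": _jitter([1, 2, 1, 2, 1, 2, 1, 2])})
        with pytest.raises(ConfigurationError):
            pt.kmeans_clusters(mat, k=5)

    def test_beats_random_assignments(self):
        """Returned inertia <= inertia of 100 random label assignments (10 features)."""
        rng = np.random.default_rng(8)
        rows = {f"f{i}": list(np.exp2(rng.normal(0, 1, 8))) for i in range(10)}
        mat = make_matrix(rows)
        labels = pt.kmeans_clusters(mat, k=3, seed=0)
        z = _standardize_rows(mat.log2()).to_numpy()

        def inertia(lab):
            tot = 0.0
            for c in set(lab):
                pts = z[np.asarray(lab) == c]
                tot += ((pts - pts.mean(axis=0)) ** 2).sum()
            return tot

        ours = inertia(labels.to_numpy())
        for _ in range(100):
            rand = rng.integers(0, 3, size=10)
            assert ours <= inertia(rand) + 1e-9


class TestSDFilter:
    def test_constant_row_removed(self):
        mat = make_matrix({"flat": [3.0] * 8, "varying": _jitter([1, 1, 2, 2, 8, 8, 1, 1])})
        out = pt.log2_sd_filter(mat, sd_min=0.0)
        assert list(out.values.index) == ["varying"]

    def test_hand_computed_sd(self):
        # log2 values (-1,-1,1,1) over 4 samples -> sd = sqrt(4/3) = 1.1547
        mat = make_matrix({"f1": [0.5, 0.5, 2.0, 2.0]}, reps=1)
        for sd_min in (0.2, 0.5):
            assert list(pt.log2_sd_filter(mat, sd_min).values.index) == ["f1"]
        assert np.log2(mat.values.loc["f1"]).std(ddof=1) == pytest.approx(
            np.sqrt(4 / 3), abs=1e-9
        )

    def test_infinite_threshold_empties(self, default_dataset):
        rel = pt.relative_quantify(default_dataset.proteome)
        assert pt.log2_sd_filter(rel, sd_min=np.inf).n_features == 0


class TestFuzzyCMeans:
    def test_membership_rows_sum_to_one(self, default_dataset):
        rel = pt.relative_quantify(default_dataset.proteome)
        sc = pt.fuzzy_cmeans(rel, c=4, seed=0)
        np.testing.assert_allclose(sc.membership.sum(axis=1), 1.0, atol=1e-9)

    def test_duplicate_rows_get_identical_memberships(self):
        rng = np.random.default_rng(3)
        base = list(np.exp2(rng.normal(0, 1, 8)))
        rows = {f"f{i}": list(np.exp2(rng.normal(0, 1, 8))) for i in range(8)}
        rows["dupA"] = base
        rows["dupB"] = base
        sc = pt.fuzzy_cmeans(make_matrix(rows), c=3, seed=0)
        np.testing.assert_allclose(
            sc.membership.loc["dupA"], sc.membership.loc["dupB"], atol=1e-9
        )

    def test_objective_non_increasing(self, default_dataset):
        rel = pt.relative_quantify(default_dataset.proteome)
        sc = pt.fuzzy_cmeans(rel, c=5, seed=0)
        path = np.asarray(sc.objective_path)
        assert (np.diff(path) <= 1e-8).all()

    def test_separable_templates_recovered_and_confident(self, noise_free_config):
        """40 noise-free features, two antipodal templates, c=2, m=1.5."""
        cfg = pt.SimulationConfig(
            **{**noise_free_config.__dict__, "n_proteins": 40, "n_sites": 0,
               "fraction_per_template": (0.5, 0.5)}
        )
        mat, truth = pt.simulate_proteome(cfg)
        rel = pt.relative_quantify(mat)
        sc = pt.fuzzy_cmeans(rel, c=2, m=1.5, seed=0)
        assert (sc.membership.max(axis=1) > 0.95).all()
        tab = pd.crosstab(truth.protein_template[sc.membership.index], sc.hard)
        assert (tab.to_numpy() > 0).sum() == 2

    def test_agrees_with_multistart_reference(self, default_dataset):
        """Partition matches an independent multi-start fuzzy c-means on separable data."""
        rel = pt.relative_quantify(default_dataset.proteome)
        planted = default_dataset.truth.protein_template
        rel = rel.subset(planted.index[planted >= 0])
        sc = pt.fuzzy_cmeans(rel, c=2, seed=0)

        z = _standardize_rows(rel.log2()).to_numpy()
        best, best_obj = None, np.inf
        rng = np.random.default_rng(99)
        for _ in range(50):
            centroids = z[rng.choice(len(z), 2, replace=False)].copy()
            for _ in range(200):
                d2 = ((z[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
                d2 = np.maximum(d2, 1e-300)
                u = (1 / d2) / (1 / d2).sum(axis=1, keepdims=True)
                um = u**2
                new = (um.T @ z) / um.sum(axis=0)[:, None]
                if np.abs(new - centroids).max() < 1e-9:
                    centroids = new
                    break
                centroids = new
            obj = float((um * d2).sum())
            if obj < best_obj:
                best_obj, best = obj, u.argmax(axis=1)
        ours = sc.hard.to_numpy()
        agreement = max(np.mean(ours == best), np.mean(ours == 1 - best))
        assert agreement == 1.0

    def test_fuzzifier_must_exceed_one(self, default_dataset):
        rel = pt.relative_quantify(default_dataset.proteome)
        with pytest.raises(ConfigurationError):
            pt.fuzzy_cmeans(rel, c=2, m=1.0)


class TestTrendSelection:
    def _selection_for(self, centroid_means):
        """Build a 1-cluster SoftClustering whose group means are as given."""
        samples = [f"{g}{r}" for g in GROUPS for r in (1, 2)]
        groups = pd.Series({s: s.rstrip("12") for s in samples})
        centroids = pd.DataFrame(
            [[centroid_means[GROUPS.index(groups[s])] for s in samples]],
            columns=samples,
        )
        membership = pd.DataFrame({0: [1.0]}, index=["f1"])
        sc = pt.cluster.SoftClustering(
            centroids=centroids, membership=membership, fuzzifier=2.0,
            converged=True, n_iter=1,
        )
        return pt.select_trend_clusters(sc, groups)

    @pytest.mark.parametrize(
        "means,selected,label",
        [
            ((0, -0.5, 1.2, -0.7), True, "up-in-M-reversed"),
            ((0, 0.4, -1.0, 0.6), True, "down-in-M-reversed"),
            ((0, 0.3, 0.8, 1.0), False, ""),
            ((0, 0.01, 1.0, -0.5), False, ""),  # |CT-C| below epsilon
        ],
    )
    def test_rule_application(self, means, selected, label):
        sel = self._selection_for(means)
        assert (0 in sel.selected_clusters) == selected
        assert sel.cluster_table.loc[0, "direction"] == label
        if selected:
            assert sel.selected_features == ["f1"]

    def test_selected_sign_invariant(self, default_dataset):
        """Selected clusters satisfy sign(CT-C) = sign(MT-M) = -sign(M-C)."""
        rel = pt.relative_quantify(default_dataset.proteome)
        sc = pt.fuzzy_cmeans(pt.log2_sd_filter(rel, 0.2), c=5, seed=0)
        sel = pt.select_trend_clusters(sc, rel.groups)
        for ci in sel.selected_clusters:
            row = sel.cluster_table.loc[ci]
            assert np.sign(row["d_CT_C"]) == np.sign(row["d_MT_M"])
            assert np.sign(row["d_M_C"]) == -np.sign(row["d_MT_M"])
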