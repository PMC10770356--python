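"""Relative quantification, phospho correction and QC behave per contract."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import phostrend as pt
from phostrend.matrix import ConfigurationError
from phostrend.quantify import completeness_filter, residue_class_stats
from tests.conftest import make_matrix


class TestRelativeQuantify:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ([2, 4, 6, 4, 2, 4, 6, 4], None),  # mean 4 -> /4
            ([5] * 8, [1.0] * 8),  # constant row -> all ones
        ],
    )
    def test_examples(self, row, expected):
        mat = make_matrix({"f1": row})
        rel = pt.relative_quantify(mat)
        if expected is None:
            expected = [v / np.mean(row) for v in row]
        np.testing.assert_allclose(rel.values.loc["f1"], expected, rtol=1e-12)

    def test_row_means_are_one(self, default_dataset):
        rel = pt.relative_quantify(default_dataset.proteome)
        np.testing.assert_allclose(rel.values.mean(axis=1), 1.0, atol=1e-12)

    def test_idempotent(self, default_dataset):
        rel = pt.relative_quantify(default_dataset.proteome)
        again = pt.relative_quantify(rel)
        pd.testing.assert_frame_equal(rel.values, again.values)

    @given(
        st.lists(
            st.lists(st.floats(0.01, 1e6), min_size=8, max_size=8),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_row_mean_property(self, rows):
        mat = make_matrix({f"f{i}": r for i, r in enumerate(rows)})
        rel = pt.relative_quantify(mat)
        np.testing.assert_allclose(rel.values.mean(axis=1), 1.0, rtol=1e-9)

    def test_all_zero_row_excluded_with_warning(self, caplog):
        mat = make_matrix({"ok": [1, 2, 3, 4, 1, 2, 3, 4], "zero": [0] * 8})
        with caplog.at_level("WARNING"):
            rel = pt.relative_quantify(mat)
        assert list(rel.values.index) == ["ok"]
        assert "zero" in caplog.text

    def test_mean_uses_nonmissing_entries(self):
        mat = make_matrix({"f1": [2, 4, np.nan, np.nan, 2, 4, 2, 4]})
        rel = pt.relative_quantify(mat)
        assert rel.values.loc["f1"].mean() == pytest.approx(1.0)


class TestPhosphoCorrection:
    def test_site_over_protein_ratio(self):
        sites = pd.DataFrame(
            {"protein_id": ["P1"], "residue": ["S"], "position": [10]},
            index=["P1_S10"],
        )
        site = make_matrix({"P1_S10": [1.2] * 8}, level="phosphosite", sites=sites)
        prot = make_matrix({"P1": [1.5] * 8})
        out = pt.correct_phospho_by_protein(site, prot)
        np.testing.assert_allclose(out.values.loc["P1_S10"], 0.8, rtol=1e-12)

    def test_proportional_site_becomes_constant(self):
        sites = pd.DataFrame(
            {"protein_id": ["P1"], "residue": ["T"], "position": [3]}, index=["s1"]
        )
        prot_vals = [2.0, 4.0, 8.0, 2.0, 4.0, 2.0, 8.0, 2.0]
        prot = pt.relative_quantify(make_matrix({"P1": prot_vals}))
        site = pt.relative_quantify(
            make_matrix({"s1": [3 * v for v in prot_vals]},
                        level="phosphosite", sites=sites)
        )
        out = pt.correct_phospho_by_protein(site, prot)
        vals = out.values.loc["s1"].to_numpy()
        np.testing.assert_allclose(vals, vals[0], rtol=1e-12)

    def test_correction_removes_protein_trend(self, noise_free_config):
        """Protein-level (0,0,1,0)-like trends vanish from corrected M/C folds."""
        ds = pt.simulate_dataset(noise_free_config)
        rel_p = pt.relative_quantify(ds.proteome)
        rel_s = pt.relative_quantify(ds.phospho)
        corrected = pt.relative_quantify(pt.correct_phospho_by_protein(rel_s, rel_p))
        null_sites = ds.truth.site_template.index[ds.truth.site_template < 0]
        trended_parents = null_sites[
            ds.truth.protein_template[ds.truth.site_protein[null_sites]].to_numpy() >= 0
        ]
        if len(trended_parents) == 0:
            pytest.skip("no null site on a trended parent at this seed")
        raw_fc = pt.contrast(rel_s, "M", "C").table["FC"]
        cor_fc = pt.contrast(corrected, "M", "C").table["FC"]
        assert (np.abs(np.log2(cor_fc[trended_parents])) < 1e-9).all()
        assert (np.abs(np.log2(raw_fc[trended_parents])) > 0.5).all()

    def test_unquantified_parent_passes_through(self, caplog):
        sites = pd.DataFrame(
            {"protein_id": ["P9"], "residue": ["S"], "position": [1]}, index=["s1"]
        )
        site = make_matrix({"s1": [1.1] * 8}, level="phosphosite", sites=sites)
        prot = make_matrix({"P1": [1.0] * 8})
        with caplog.at_level("WARNING"):
            out = pt.correct_phospho_by_protein(site, prot)
        np.testing.assert_allclose(out.values.loc["s1"], 1.1)
        assert not out.sites.loc["s1", "corrected"]


class TestRSD:
    def test_constant_group_has_zero_rsd(self):
        qc = pt.compute_rsd(make_matrix({"f1": [1, 1] * 4}))
        assert (qc.rsd.loc["f1"] == 0).all()

    def test_hand_computed_value(self):
        # group values (0.9, 1.1): sd = sqrt(0.02) with n-1, mean = 1.0
        qc = pt.compute_rsd(make_matrix({"f1": [0.9, 1.1] * 4}))
        assert qc.rsd.loc["f1", "C"] == pytest.approx(np.sqrt(0.02), abs=1e-9)

    def test_noise_free_simulation_passes_qc(self, noise_free_config):
        mat, _ = pt.simulate_proteome(noise_free_config)
        qc = pt.compute_rsd(pt.relative_quantify(mat))
        np.testing.assert_allclose(qc.rsd.to_numpy(), 0.0, atol=1e-9)
        assert qc.rsd_summary["pass"].all()


class TestPCA:
    def test_identical_samples_collapse(self):
        rows = {f"f{i}": [float(i + 1)] * 8 for i in range(5)}
        qc = pt.pca_samples(pt.relative_quantify(make_matrix(rows)), n_components=2)
        dists = np.ptp(qc.pca_coords.to_numpy(), axis=0)
        np.testing.assert_allclose(dists, 0.0, atol=1e-9)

    def test_explained_variance_sums_to_one(self, default_dataset):
        rel = pt.relative_quantify(default_dataset.proteome)
        qc = pt.pca_samples(rel, n_components=rel.n_samples - 1)
        assert qc.explained_variance.sum() == pytest.approx(1.0, abs=1e-9)

    def test_groups_separate_with_strong_templates(self, default_dataset):
        rel = pt.relative_quantify(default_dataset.proteome)
        qc = pt.pca_samples(rel, n_components=2)
        coords = qc.pca_coords
        groups = rel.groups
        within, between = [], []
        for a in coords.index:
            for b in coords.index:
                if a >= b:
                    continue
                d = np.linalg.norm(coords.loc[a] - coords.loc[b])
                (within if groups[a] == groups[b] else between).append(d)
        assert np.mean(within) < np.mean(between)

    def test_feature_order_invariance(self, default_dataset):
        rel = pt.relative_quantify(default_dataset.proteome)
        shuffled = rel.subset(rel.values.index[::-1])
        c1 = pt.pca_samples(rel, 2).pca_coords
        c2 = pt.pca_samples(shuffled, 2).pca_coords
        np.testing.assert_allclose(c1.to_numpy(), c2.to_numpy(), atol=1e-8)

    def test_too_many_components_rejected(self):
        mat = make_matrix({"f1": [1, 2] * 4, "f2": [2, 1] * 4})
        with pytest.raises(ConfigurationError):
            pt.pca_samples(pt.relative_quantify(mat), n_components=5)


class TestCompletenessAndResidues:
    def test_completeness_filter_drops_sparse_features(self):
        mat = make_matrix(
            {"full": [1] * 8, "sparse": [1, np.nan, np.nan, np.nan, np.nan, 1, np.nan, np.nan]}
        )
        kept = completeness_filter(mat, min_fraction=0.5)
        assert list(kept.values.index) == ["full"]

    def test_residue_percentages_round_to_one_decimal(self):
        sites = pd.DataFrame(
            {
                "residue": ["S"] * 6799 + ["T"] * 984 + ["Y"] * 118,
                "protein_id": "P1",
                "position": range(1, 7902),
            }
        )
        stats_tbl = residue_class_stats(sites)
        assert stats_tbl["count"].tolist() == [6799, 984, 118]
        # 6799/7901 = 86.052% -> 86.1 under standard one-decimal rounding
        assert stats_tbl["percent"].tolist() == [86.1, 12.5, 1.5]
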