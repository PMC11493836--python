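"""Cohort biomarker statistics on the packaged serum table."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gslmrm.cohort import (
    PATIENT_GROUPS,
    gm2_gm3_ratio,
    group_compare,
    grubbs_critical_value,
    grubbs_filter,
    heatmap_zscores,
    load_cohort_table,
    pca,
    species_columns,
)

GM_SPECIES = ["GM1 d36:1", "GM2 d36:1", "GM3 d36:1"]


class TestFixture:
    def test_loads_39_by_7(self, cohort_table):
        assert len(cohort_table) == 39
        assert len(species_columns(cohort_table)) == 7
        assert (cohort_table["group"] == "control").sum() == 36

    def test_control_class_means_match_reference(self, cohort_table):
        ctrl = cohort_table[cohort_table["group"] == "control"]
        assert round(ctrl["GM3 d36:1"].mean(), 1) == 397.4
        assert round(ctrl["GD3 d36:1"].mean(), 1) == 235.9
        assert round(ctrl["GM2 d36:1"].mean(), 1) == 203.1

    def test_unknown_group_label_rejected(self, tmp_path, cohort_table):
        bad = cohort_table.copy()
        bad.loc[0, "group"] = "mystery"
        p = tmp_path / "bad.csv"
        bad.to_csv(p, index=False)
        with pytest.raises(ValueError, match="mystery"):
            load_cohort_table(p)


class TestGrubbs:
    def test_gross_outlier_removed(self):
        kept, removed = grubbs_filter([1.0, 1.0, 1.1, 0.9, 100.0], alpha=0.05)
        assert removed == ["4"]
        assert 100.0 not in kept

    def test_symmetric_data_untouched(self):
        kept, removed = grubbs_filter([1.0, 2.0, 3.0, 4.0, 5.0], alpha=0.05)
        assert removed == [] and len(kept) == 5

    def test_small_n_no_filtering(self):
        kept, removed = grubbs_filter([1.0, 100.0], alpha=0.05)
        assert removed == [] and len(kept) == 2

    @pytest.mark.parametrize(
        "n, alpha, expected",
        [(10, 0.05, 2.290), (20, 0.05, 2.709), (30, 0.05, 2.908), (10, 0.01, 2.482)],
    )
    def test_critical_values_match_published_tables(self, n, alpha, expected):
        assert grubbs_critical_value(n, alpha) == pytest.approx(expected, abs=2e-3)

    @pytest.mark.parametrize("alpha", [0.01, 0.05])
    def test_agrees_with_direct_formula_n_3_to_50(self, alpha):
        """Filtering decisions agree with a brute-force oracle built from
        the t-quantile critical-value formula."""
        rng = np.random.default_rng(17)
        for n in range(3, 51):
            x = rng.normal(0, 1, n)
            if n % 3 == 0:
                x[0] += 6.0  # plant an outlier in a third of the draws
            kept, removed = grubbs_filter(x, alpha)
            # oracle: single-pass recursive max-deviation screening
            y = list(x)
            expect_removed = 0
            while len(y) >= 3:
                arr = np.array(y)
                sd = arr.std(ddof=1)
                if sd == 0:
                    break
                g = np.abs(arr - arr.mean()).max() / sd
                tq = sps.t.ppf(1 - alpha / (2 * len(arr)), len(arr) - 2)
                gcrit = (
                    (len(arr) - 1)
                    / np.sqrt(len(arr))
                    * np.sqrt(tq**2 / (len(arr) - 2 + tq**2))
                )
                if g <= gcrit:
                    break
                y.remove(arr[np.argmax(np.abs(arr - arr.mean()))])
                expect_removed += 1
            assert len(removed) == expect_removed, (n, alpha)


class TestGroupCompare:
    def test_gm2_fold_change_is_ten_on_reference_cohort(self, cohort_table):
        res = {r.species_id: r for r in group_compare(cohort_table)}
        assert round(res["GM2 d36:1"].fold_change_mean, 1) == 10.0

    def test_fold_directions_match_disease_biology(self, cohort_table):
        """GM2 and GM1 accumulate, GM3 falls, in hexosaminidase deficiency."""
        res = {r.species_id: r for r in group_compare(cohort_table)}
        assert res["GM2 d36:1"].fold_change_mean > 5
        assert res["GM1 d36:1"].fold_change_mean > 3
        assert res["GM3 d36:1"].fold_change_mean == pytest.approx(0.57, abs=0.01)
        assert res["GM2 d36:1"].p_adjusted < 0.01
        assert res["GM1 d36:1"].p_adjusted < 0.01
        assert res["GM3 d36:1"].p_adjusted < 0.01

    def test_adjusted_p_not_smaller_than_raw(self, cohort_table):
        for r in group_compare(cohort_table):
            assert r.p_adjusted >= r.p_value - 1e-15
        for r in group_compare(cohort_table, adjust="bonferroni"):
            assert r.p_adjusted >= r.p_value - 1e-15

    def test_identical_groups_null(self, cohort_table):
        t = cohort_table.copy()
        ctrl = t[t["group"] == "control"].head(6).copy()
        dup = ctrl.copy()
        dup["group"] = "tay_sachs"
        dup["sample_id"] = dup["sample_id"] + "_p"
        null = pd.concat([ctrl, dup], ignore_index=True)
        for r in group_compare(null):
            assert r.fold_change_mean == pytest.approx(1.0)
            assert r.p_value == pytest.approx(1.0)

    def test_permuted_labels_give_uniform_pvalues(self, cohort_table):
        """Permutation oracle: under random label assignment the t-test
        p-value distribution is approximately uniform."""
        x = cohort_table["GD3 d36:1"].to_numpy(float)
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(500):
            perm = rng.permutation(x)
            ps.append(sps.ttest_ind(perm[:3], perm[3:], equal_var=True).pvalue)
        ps = np.array(ps)
        assert sps.kstest(ps, "uniform").statistic < 0.1
        assert 0.01 <= (ps < 0.05).mean() <= 0.10

    def test_grubbs_prefilter_reports_removals(self, cohort_table):
        res = {
            r.species_id: r
            for r in group_compare(cohort_table, grubbs_alpha=0.05)
        }
        all_removed = [x for r in res.values() for x in r.outliers_removed]
        for r in res.values():
            assert r.n_control == 36 - sum(
                1 for sid in r.outliers_removed if sid.startswith("CS")
            )
        # removing outliers can only have happened on the control side
        assert all(sid.startswith("CS") for sid in all_removed)

    def test_welch_option_changes_statistic(self, cohort_table):
        pooled = {r.species_id: r.t_statistic for r in group_compare(cohort_table)}
        welch = {
            r.species_id: r.t_statistic
            for r in group_compare(cohort_table, welch=True)
        }
        assert any(abs(pooled[s] - welch[s]) > 1e-6 for s in pooled)


class TestRatio:
    def test_tsd01_ratio_matches_direct_division(self, cohort_table):
        ratios, _ = gm2_gm3_ratio(cohort_table)
        v = ratios.set_index("sample_id").loc["TSD01", "gm2_gm3_ratio"]
        assert v == pytest.approx(2905.3 / 251.7, rel=1e-9)
        assert round(v, 2) == 11.54

    def test_group_fold_changes_on_fixture(self, cohort_table):
        _, summary = gm2_gm3_ratio(cohort_table)
        assert summary["fold_change_mean"] == pytest.approx(16.36, abs=0.01)
        assert summary["fold_change_median"] == pytest.approx(21.15, abs=0.01)

    def test_equal_species_unit_ratio(self, cohort_table):
        t = cohort_table.copy()
        t["GM2 d36:1"] = t["GM3 d36:1"]
        ratios, summary = gm2_gm3_ratio(t)
        assert (ratios["gm2_gm3_ratio"] == 1.0).all()
        assert summary["fold_change_mean"] == 1.0

    def test_missing_column_rejected(self, cohort_table):
        with pytest.raises(KeyError):
            gm2_gm3_ratio(cohort_table.drop(columns=["GM2 d36:1"]))


class TestPCA:
    def test_patients_separate_from_controls_on_pc1(self, cohort_table):
        res = pca(cohort_table, species=GM_SPECIES)
        pat = cohort_table["group"].isin(PATIENT_GROUPS).to_numpy()
        pc1 = res.scores["PC1"].to_numpy()
        assert pc1[pat].min() > pc1[~pat].max()

    def test_scores_times_loadings_reconstructs_autoscaled_matrix(self, cohort_table):
        res = pca(cohort_table, species=GM_SPECIES)
        X = cohort_table[GM_SPECIES].to_numpy(float)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.abs(recon - Z).max() < 1e-8

    def test_loadings_orthonormal_variance_non_increasing(self, cohort_table):
        res = pca(cohort_table)
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)
        evr = res.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1 + 1e-9

    def test_matches_sklearn_oracle(self, cohort_table):
        """Independent cross-check of scores against scikit-learn."""
        from sklearn.decomposition import PCA as SkPCA

        X = cohort_table[GM_SPECIES].to_numpy(float)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        ours = pca(cohort_table, species=GM_SPECIES).scores.to_numpy()
        theirs = SkPCA(n_components=3).fit_transform(Z)
        for j in range(3):
            # sign conventions may differ per component
            assert np.allclose(ours[:, j], theirs[:, j], atol=1e-8) or np.allclose(
                ours[:, j], -theirs[:, j], atol=1e-8
            )

    def test_rank_one_data_concentrates_variance(self):
        rng = np.random.default_rng(1)
        informative = rng.normal(0, 5, 30)
        t = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(30)],
                "group": "control",
                "A": informative,
                "B": informative * 2.0 + 1.0,
            }
        )
        res = pca(t, species=["A", "B"])
        assert res.explained_variance_ratio[0] > 0.999

    def test_autoscaled_total_variance_equals_species_count(self, cohort_table):
        res = pca(cohort_table)
        X = cohort_table[species_columns(cohort_table)].to_numpy(float)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        assert np.sum(np.var(Z, axis=0, ddof=1)) == pytest.approx(Z.shape[1])

    def test_too_few_species_or_samples_rejected(self, cohort_table):
        with pytest.raises(ValueError):
            pca(cohort_table, species=["GM2 d36:1"])
        with pytest.raises(ValueError):
            pca(cohort_table.head(2))


class TestZScores:
    def test_columns_standardized(self, cohort_table):
        z = heatmap_zscores(cohort_table)
        assert np.allclose(z.mean(), 0.0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1.0, atol=1e-12)

    def test_tsd01_is_extreme_in_gm2(self, cohort_table):
        z = heatmap_zscores(cohort_table)
        assert z["GM2 d36:1"].idxmax() == "TSD01"

    def test_constant_column_rejected_naming_species(self, cohort_table):
        t = cohort_table.copy()
        t["GM2 d36:1"] = 1.0
        with pytest.raises(ValueError, match="GM2 d36:1"):
            heatmap_zscores(t)
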