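"""Per-metabolite ANOVA, Bonferroni, PCA and class summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexnet.metabolomics import (
    MetaboliteTable,
    anova_per_metabolite,
    bonferroni_adjust,
    class_fold_change_summary,
    pca_scores,
)


def two_pass_anova_oracle(groups):
    """Textbook sums-of-squares decomposition."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    F = (ss_between / df_b) / (ss_within / df_w)
    return F, stats.f.sf(F, df_b, df_w)


def _table(values, groups, classes=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    mets = [f"m{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return MetaboliteTable(
        concentrations=pd.DataFrame(values, index=mets, columns=samples),
        classes=pd.Series(classes or ["AA"] * len(mets), index=mets),
        groups=pd.Series(groups, index=samples),
    )


class TestAnova:
    def test_matches_two_pass_oracle(self):
        vals = [1, 2, 3, 2, 3, 4, 3, 4, 5]
        table = _table([vals], ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        res = anova_per_metabolite(table, log_transform=False)
        F_exp, p_exp = two_pass_anova_oracle([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res["F"].iloc[0] == pytest.approx(F_exp, abs=1e-12)
        assert res["p"].iloc[0] == pytest.approx(p_exp, abs=1e-12)

    def test_two_groups_equal_t_squared(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 6)
        table = _table([np.concatenate([a, b]) + 10], ["a"] * 6 + ["b"] * 6)
        res = anova_per_metabolite(table, log_transform=False)
        t = stats.ttest_ind(a + 10, b + 10, equal_var=True).statistic
        assert res["F"].iloc[0] == pytest.approx(t**2, abs=1e-10)

    def test_all_equal_observations_are_flagged(self):
        table = _table([[7.0] * 8], ["a"] * 4 + ["b"] * 4)
        res = anova_per_metabolite(table)
        assert bool(res["degenerate"].iloc[0])
        assert res["p"].iloc[0] == 1.0

    def test_null_f_matches_its_expectation(self):
        # E[F] under H0 is d2/(d2-2) with d2 the within-group df (here 9)
        rng = np.random.default_rng(1)
        vals = rng.normal(5, 1, size=(300, 12))
        table = _table(vals, ["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        res = anova_per_metabolite(table, log_transform=False)
        assert res["F"].mean() == pytest.approx(9 / 7, abs=0.25)

    def test_needs_two_replicates_per_group(self):
        table = _table([[1.0, 2.0, 3.0]], ["a", "a", "b"])
        with pytest.raises(ValueError, match="replicates"):
            anova_per_metabolite(table)


class TestBonferroni:
    def test_panel_scale_arithmetic(self):
        assert bonferroni_adjust(np.array([0.0001]), m=188)[0] == pytest.approx(0.0188)

    def test_cap_at_one(self):
        assert bonferroni_adjust(np.array([0.5]), m=188)[0] == 1.0

    def test_m_one_is_identity(self):
        assert bonferroni_adjust(np.array([0.3]), m=1)[0] == pytest.approx(0.3)

    def test_family_wise_error_controlled_under_null(self):
        rng = np.random.default_rng(2)
        fwe = 0
        runs = 500
        for _ in range(runs):
            p = rng.uniform(size=188)
            fwe += (bonferroni_adjust(p) < 0.05).any()
        assert fwe / runs <= 0.07

    def test_raw_rejection_rate_under_null(self):
        # averaged over replicate panels so the binomial noise of a single
        # 188-metabolite draw does not dominate
        fracs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            vals = 2.0 ** rng.normal(5, 0.4, size=(188, 24))
            table = _table(vals, [g for g in ("a", "b", "c", "d") for _ in range(6)])
            res = anova_per_metabolite(table)
            fracs.append((res["p"] < 0.05).mean())
        assert 0.03 <= np.mean(fracs) <= 0.07


class TestPca:
    def test_duplicated_samples_have_identical_scores(self):
        rng = np.random.default_rng(4)
        vals = 2.0 ** rng.normal(4, 1, size=(30, 4))
        vals = np.column_stack([vals, vals[:, 0]])
        table = _table(vals, ["a", "a", "b", "b", "a"])
        scores, _ = pca_scores(table)
        assert np.allclose(
            scores.drop(columns="group").iloc[0], scores.drop(columns="group").iloc[4], atol=1e-9
        )

    def test_separated_groups_have_high_silhouette(self):
        from sklearn.metrics import silhouette_score

        from coexnet.simulate import default_metabolite_panel, simulate_metabolites

        panel = default_metabolite_panel()
        table, _ = simulate_metabolites(
            n_groups=2,
            effect_metabolites=set(list(panel)[:60]),
            effect_log2fc=2.0,
            seed=5,
        )
        scores, _ = pca_scores(table)
        labels = scores["group"].to_numpy()
        assert silhouette_score(scores[["PC1", "PC2"]], labels) > 0.5

    def test_reconstruction_identity_without_scaling(self):
        rng = np.random.default_rng(6)
        vals = 2.0 ** rng.normal(4, 1, size=(10, 6))
        table = _table(vals, ["a", "a", "a", "b", "b", "b"])
        from sklearn.decomposition import PCA

        data = np.log2(vals).T
        centred = data - data.mean(axis=0)
        pca = PCA(svd_solver="full").fit(centred)
        recon = pca.inverse_transform(pca.transform(centred))
        assert np.allclose(recon, centred, atol=1e-9)

    def test_scores_invariant_to_metabolite_order_up_to_sign(self):
        rng = np.random.default_rng(7)
        vals = 2.0 ** rng.normal(4, 1, size=(20, 8))
        groups = ["a"] * 4 + ["b"] * 4
        s1, _ = pca_scores(_table(vals, groups))
        s2, _ = pca_scores(_table(vals[::-1], groups))
        for pc in ("PC1", "PC2"):
            a, b = s1[pc].to_numpy(), s2[pc].to_numpy()
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_constant_matrix_is_an_error(self):
        table = _table(np.full((5, 6), 3.0), ["a"] * 3 + ["b"] * 3)
        with pytest.raises(ValueError, match="constant"):
            pca_scores(table)


class TestClassSummary:
    def _result(self):
        vals = np.array(
            [
                [10, 10, 20, 20],   # AA: ratio 2 -> log2 1
                [8, 8, 8, 8],       # AA: ratio 1 -> 0
                [100, 100, 25, 25], # H1: ratio 1/4 -> -2
            ],
            dtype=float,
        )
        table = _table(vals, ["a", "a", "b", "b"], classes=["AA", "AA", "H1"])
        return anova_per_metabolite(table, log_transform=False)

    def test_hand_set_means(self):
        summary = class_fold_change_summary(self._result(), "a", use_bonferroni=False)
        aa = summary[(summary["class"] == "AA") & (summary["group"] == "b")].iloc[0]
        h1 = summary[(summary["class"] == "H1") & (summary["group"] == "b")].iloc[0]
        assert aa["mean_log2_ratio"] == pytest.approx(0.5)   # mean of (1, 0)
        assert h1["mean_log2_ratio"] == pytest.approx(-2.0)  # single member class
        assert h1["n_metabolites"] == 1

    def test_all_ratios_one_give_zero_summaries(self):
        vals = np.array([[5.0, 5, 5, 5], [9.0, 9, 9, 9]])
        table = _table(vals, ["a", "a", "b", "b"])
        res = anova_per_metabolite(table, log_transform=False)
        summary = class_fold_change_summary(res, "a")
        assert np.allclose(summary["mean_log2_ratio"], 0.0)

    def test_class_without_significant_members_reports_nan_not_error(self):
        summary = class_fold_change_summary(self._result(), "a", use_bonferroni=True)
        # degenerate flat metabolite never significant; summary still present
        assert len(summary) == 2
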