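"""ANCOVA machinery: design, elimination, outliers, LS-means, slopes."""

import numpy as np
import pandas as pd
import pytest

from finsex import association as assoc


def _balanced_data(n_per_cell=8, noise=0.5, seed=0, effects=None):
    effects = effects or {}
    return assoc.simulate_intensity_data(
        n_per_cell=n_per_cell, noise_sd=noise, seed=seed, **effects
    )


class TestFitFull:
    def test_reduces_to_cell_means_without_covariate_effects(self):
        # strong factor effects, no covariate effects: LS-means track cell means
        data = _balanced_data(
            n_per_cell=60,
            noise=0.3,
            effects={"sex_effect": 1.0, "interaction": -0.4},
            seed=1,
        )
        fit = assoc.fit_full(assoc.AncovaSpec(), data)
        lsm = assoc.ls_means(fit).set_index("cell")
        cells = data.groupby(["group", "true_sex"])["z"].mean()
        for (g, s), mean in cells.items():
            assert abs(lsm.loc[f"{g}*{s}", "estimate"] - mean) < 0.2

    def test_requires_two_obs_per_cell(self):
        data = _balanced_data(n_per_cell=5)
        data = data[~((data.group == "control") & (data.true_sex == "M"))]
        with pytest.raises(ValueError, match="cell"):
            assoc.fit_full(assoc.AncovaSpec(), data)

    def test_degenerate_covariate_rejected(self):
        data = _balanced_data(n_per_cell=5)
        data["body_weight_g"] = 0.4
        with pytest.raises(ValueError, match="degenerate"):
            assoc.fit_full(assoc.AncovaSpec(), data)

    def test_duplicate_covariate_term_is_aliasing_error(self):
        data = _balanced_data(n_per_cell=6)
        spec = assoc.AncovaSpec(max_poly_degree=1)
        terms = spec.terms() + [assoc.Term("x^1", parents=())]
        with pytest.raises(assoc.AliasingError, match="x\\^1"):
            assoc.fit_terms(spec, data, terms)


class TestBackwardElimination:
    def test_marginality_blocks_parents_of_kept_interactions(self):
        data = _balanced_data(n_per_cell=10, seed=3)
        fit = assoc.fit_full(assoc.AncovaSpec(max_poly_degree=2), data)
        removable = {t.name for t in assoc._removable(fit.terms)}
        # main effects and low powers are shielded while children are present
        assert "sex" not in removable
        assert "x^1" not in removable
        assert "sex:x^2" in removable and "treatment:x^2" in removable

    def test_drops_null_interaction_keeps_real_sex_by_size_slope(self):
        hits_drop, hits_keep = 0, 0
        reps = 30
        for r in range(reps):
            data = _balanced_data(
                n_per_cell=100,
                noise=0.6,
                seed=100 + r,
                effects={"sex_effect": 0.8, "b1": 5.0, "b2": 3.0},
            )
            final = assoc.backward_eliminate(assoc.fit_full(assoc.AncovaSpec(), data))
            kept = set(final.term_names)
            hits_drop += "treatment:sex" not in kept
            hits_keep += "sex:x^1" in kept
        assert hits_keep == reps
        assert hits_drop >= int(0.9 * reps)

    def test_null_data_usually_ends_near_intercept_only(self):
        kept_counts = []
        for r in range(40):
            data = _balanced_data(n_per_cell=30, noise=1.0, seed=500 + r)
            final = assoc.backward_eliminate(assoc.fit_full(assoc.AncovaSpec(), data))
            kept_counts.append(len(final.terms) - 1)
        # most replicates end intercept-only; occasionally a spurious term
        # survives (and marginality then shields its parents)
        assert np.median(kept_counts) == 0
        assert np.mean(kept_counts) < 2.5
        assert np.mean(np.asarray(kept_counts) == 0) >= 0.5

    def test_can_return_intercept_only(self):
        data = _balanced_data(n_per_cell=20, noise=1.0, seed=77)
        final = assoc.backward_eliminate(assoc.fit_full(assoc.AncovaSpec(), data))
        assert "Intercept" in final.term_names


class TestStudentizedOutliers:
    def test_injected_shift_is_flagged(self):
        data = _balanced_data(n_per_cell=25, noise=0.5, seed=4)
        data.loc[37, "z"] += 10 * 0.5
        fit = assoc.fit_full(assoc.AncovaSpec(), data)
        flagged = assoc.studentized_outliers(fit, threshold=3.0)
        assert data.loc[37, "id"] in flagged

    def test_zero_noise_data_has_no_flags(self):
        data = _balanced_data(
            n_per_cell=10, noise=0.0, effects={"sex_effect": 1.0, "b1": 2.0}, seed=5
        )
        fit = assoc.fit_full(assoc.AncovaSpec(), data)
        assert assoc.studentized_outliers(fit) == []

    def test_filter_refits_once_and_is_stable_on_clean_data(self):
        data = _balanced_data(n_per_cell=50, noise=0.5, seed=6,
                              effects={"sex_effect": 1.0, "b1": 4.0})
        fit = assoc.fit_full(assoc.AncovaSpec(), data)
        refit, flagged = assoc.filter_outliers_and_refit(fit)
        assert len(flagged) <= 3  # ~ n * 2 * (1 - Phi(3))
        delta = np.abs(np.asarray(refit.result.params) - np.asarray(fit.result.params))
        assert np.all(delta < 3 * np.asarray(fit.result.bse))

    def test_saturated_model_rejected(self):
        data = _balanced_data(n_per_cell=2, noise=1.0, seed=7)
        spec = assoc.AncovaSpec(max_poly_degree=1)  # 7 params on n=8
        fit = assoc.fit_full(spec, data)
        with pytest.raises(ValueError, match="saturated"):
            assoc.studentized_outliers(fit)


class TestLsMeans:
    def test_matches_independent_contrast_oracle(self):
        data = _balanced_data(n_per_cell=7, noise=0.8, seed=8,
                              effects={"sex_effect": 0.5, "b1": 2.0})
        spec = assoc.AncovaSpec(max_poly_degree=1)
        fit = assoc.fit_full(spec, data)
        lsm = assoc.ls_means(fit).set_index("cell")

        # independent normal-equations computation
        g = data["group"].map({"control": 1.0, "treatment": -1.0}).to_numpy()
        s = data["true_sex"].map({"F": 1.0, "M": -1.0}).to_numpy()
        x = data["body_weight_g"].to_numpy()
        xc = x - x.mean()
        X = np.column_stack(
            [np.ones(len(data)), g, s, g * s, xc, s * xc, g * xc]
        )
        y = data["z"].to_numpy()
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        resid = y - X @ beta
        s2 = resid @ resid / (len(y) - X.shape[1])
        V = s2 * XtX_inv
        for gname, gcode in (("control", 1.0), ("treatment", -1.0)):
            for sname, scode in (("F", 1.0), ("M", -1.0)):
                L = np.array([1.0, gcode, scode, gcode * scode, 0.0, 0.0, 0.0])
                est, se = L @ beta, np.sqrt(L @ V @ L)
                row = lsm.loc[f"{gname}*{sname}"]
                assert abs(row.estimate - est) < 1e-8
                assert abs(row.se - se) < 1e-8

    def test_balanced_anova_ls_means_equal_group_means(self):
        data = _balanced_data(n_per_cell=12, noise=0.4, seed=9,
                              effects={"sex_effect": 1.2})
        fit = assoc.fit_size_anova(data, response="z")
        lsm = assoc.ls_means(fit, by=("true_sex",)).set_index("cell")
        for sex, sub in data.groupby("true_sex"):
            assert np.isclose(lsm.loc[sex, "estimate"], sub["z"].mean(), atol=1e-10)

    def test_two_group_tukey_equals_t_test(self):
        from scipy.stats import ttest_ind

        data = _balanced_data(n_per_cell=15, noise=0.7, seed=10,
                              effects={"sex_effect": 0.4})
        fit = assoc.fit_terms(
            assoc.AncovaSpec(covariate=None),
            data,
            [assoc.Term("Intercept"), assoc.Term("sex")],
        )
        lsm = assoc.ls_means(fit, by=("true_sex",))
        p_tukey = list(lsm.attrs["pairwise_p"].values())[0]
        p_t = ttest_ind(
            data.loc[data.true_sex == "F", "z"], data.loc[data.true_sex == "M", "z"]
        ).pvalue
        assert np.isclose(p_tukey, p_t, atol=1e-9)

    def test_letters_separate_distinct_cells(self):
        data = _balanced_data(n_per_cell=40, noise=0.3, seed=11,
                              effects={"sex_effect": 2.0})
        fit = assoc.fit_size_anova(data, response="z")
        lsm = assoc.ls_means(fit).set_index("cell")
        # the two sexes get disjoint letter sets; groups within sex share
        assert not set(lsm.loc["control*M", "letters"]) & set(lsm.loc["control*F", "letters"])
        assert set(lsm.loc["control*M", "letters"]) & set(lsm.loc["treatment*M", "letters"])


class TestSexSpecificSlopes:
    def test_recovers_generating_slopes(self):
        data = _balanced_data(n_per_cell=150, noise=0.4, seed=12,
                              effects={"b1": 3.0, "b2": 3.0})
        # female slope = b1 + b2, male slope = b1 - b2 (F coded +1)
        fit = assoc.fit_full(assoc.AncovaSpec(max_poly_degree=1), data)
        slopes = assoc.sex_specific_slopes(fit).set_index("true_sex")
        assert abs(slopes.loc["F", "slope"] - 6.0) < 3 * slopes.loc["F", "se"]
        assert abs(slopes.loc["M", "slope"] - 0.0) < 3 * slopes.loc["M", "se"]


def test_size_anova_recovers_weight_cell_structure():
    """Two-way ANOVA on body weight: balanced LS-means equal cell means."""
    rng = np.random.default_rng(21)
    rows = []
    means = {("control", "M"): 0.36, ("treatment", "M"): 0.40,
             ("control", "F"): 0.43, ("treatment", "F"): 0.44}
    for (g, s), m in means.items():
        for i in range(30):
            rows.append({"id": f"{g}{s}{i}", "group": g, "true_sex": s,
                         "body_weight_g": rng.normal(m, 0.05)})
    data = pd.DataFrame(rows)
    fit = assoc.fit_size_anova(data, response="body_weight_g")
    lsm = assoc.ls_means(fit).set_index("cell")
    for (g, s), m in means.items():
        cell_mean = data[(data.group == g) & (data.true_sex == s)]["body_weight_g"].mean()
        assert np.isclose(lsm.loc[f"{g}*{s}", "estimate"], cell_mean, atol=1e-10)
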