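"""Contamination resampling and the Gaussian identity-link GLM: hand ANOVA
oracle, normal-equations equivalence, aliasing, contamination algebra, and
error-rate calibration of the genus F-test."""

import numpy as np
import pandas as pd
import pytest

from introquant import (
    ContamSimConfig,
    contaminate_once,
    coverage_long_table,
    fit_glm,
    run_simulation,
    scores_from_coverage,
)


def make_cov_table(rng, n_samples=8, genera=("G", "H"), n_species=3, base=30.0, cov_lo=0.0):
    """Random long-format coverage table with positive focal coverage.

    ``cov_lo`` > 0 keeps non-focal coverages away from the zero floor so the
    allocate mode's subtracted mass is exact."""
    rows = []
    for i in range(n_samples):
        genus = genera[i % 2]
        focal = f"{genus}_sp1"
        mean_cov = {focal: base + rng.uniform(-5, 5)}
        for j in range(2, n_species + 1):
            mean_cov[f"{genus}_sp{j}"] = rng.uniform(cov_lo, 3)
        rows.append((f"s{i}", genus, focal, mean_cov))
    return coverage_long_table(rows)


def score_table(scores_by_genus):
    rows = []
    i = 0
    for genus, scores in scores_by_genus.items():
        for s in scores:
            rows.append({"sample_id": f"s{i}", "genus": genus, "species": f"{genus}_sp1", "score": s})
            i += 1
    return pd.DataFrame(rows)


class TestFitGlm:
    def test_residual_df_is_n_minus_2_for_genus_factor(self, rng):
        table = score_table({"G": rng.random(30), "H": rng.random(41)})
        fit = fit_glm(table, formula="genus")
        assert fit.df2 == 69
        assert fit.df1 == 1

    def test_f_matches_hand_anova_on_two_groups_of_three(self):
        # one-way ANOVA identity computed by hand from group means
        g = [1.0, 2.0, 3.0]
        h = [4.0, 6.0, 8.0]
        table = score_table({"G": g, "H": h})
        gm, hm = np.mean(g), np.mean(h)
        grand = np.mean(g + h)
        ss_between = 3 * ((gm - grand) ** 2 + (hm - grand) ** 2)
        ss_within = sum((x - gm) ** 2 for x in g) + sum((x - hm) ** 2 for x in h)
        f_oracle = (ss_between / 1) / (ss_within / 4)
        fit = fit_glm(table)
        assert fit.F == pytest.approx(f_oracle, rel=1e-12)
        assert (fit.df1, fit.df2) == (1, 4)

    def test_equals_normal_equations_on_full_rank_design(self, rng):
        table = score_table({"G": rng.random(10), "H": rng.random(12)})
        fit = fit_glm(table)
        X = np.column_stack(
            [np.ones(22), (table["genus"] == sorted(set(table["genus"]))[1]).to_numpy(float)]
        )
        y = table["score"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(list(fit.coefficients.values()), beta, rtol=1e-10, atol=1e-12)

    def test_within_group_constant_response_flagged_saturated(self):
        table = score_table({"G": [0.5] * 4, "H": [1.5] * 4})
        fit = fit_glm(table)
        assert "saturated" in fit.flags
        assert fit.r2 == 1.0

    def test_species_nested_in_genus_aliasing_dropped(self, rng):
        table = score_table({"G": rng.random(6), "H": rng.random(6)})
        table["species"] = [f"{g}_sp{1 + i % 2}" for i, g in enumerate(table["genus"])]
        fit = fit_glm(table, formula="genus_plus_species")
        assert fit.dropped_terms  # species indicators alias the genus column
        assert fit.df2 == 12 - (1 + fit.df1)

    def test_single_genus_rejected(self, rng):
        table = score_table({"G": rng.random(6)})
        with pytest.raises(ValueError, match="2 genera"):
            fit_glm(table)

    def test_qq_pairs_sorted_residuals_with_normal_quantiles(self, rng):
        table = score_table({"G": rng.random(8), "H": rng.random(8)})
        fit = fit_glm(table)
        assert fit.qq.shape == (16, 2)
        assert np.array_equal(fit.qq[:, 1], np.sort(fit.residuals))
        assert np.all(np.diff(fit.qq[:, 0]) > 0)


class TestContaminateOnce:
    def test_zero_fraction_keeps_scores(self, rng):
        table = make_cov_table(rng)
        cfg = ContamSimConfig(max_fraction=0.0, n_iter=1, seed=1)
        _, scores = contaminate_once(table, cfg, iteration_seed=5)
        assert np.allclose(scores["score"], scores_from_coverage(table)["score"])

    def test_uniform_fraction_bounds_scores(self, rng):
        table = make_cov_table(rng, n_samples=12)
        cfg = ContamSimConfig(max_fraction=0.09, mode="uniform_fraction", seed=1)
        raw = scores_from_coverage(table)["score"].to_numpy()
        for it in range(5):
            _, adj = contaminate_once(table, cfg, iteration_seed=it)
            a = adj["score"].to_numpy()
            assert np.all(a <= raw + 1e-12)
            assert np.all(a >= raw * (1 - 0.09) - 1e-12)

    def test_allocate_mass_balance(self, rng):
        table = make_cov_table(rng, n_samples=6, n_species=4, cov_lo=1.0)
        cfg = ContamSimConfig(max_fraction=0.09, mode="allocate", seed=1)
        adj, _ = contaminate_once(table, cfg, iteration_seed=3)
        for sample, grp in table.groupby("sample_id"):
            nonfocal = grp["species"] != grp["focal_species"]
            before = grp.loc[nonfocal, "mean_coverage"].sum()
            after = adj.loc[grp.index[nonfocal], "mean_coverage"].sum()
            # total subtracted mass equals 9% of the non-focal sum (no
            # floors hit in this fixture)
            assert before - after == pytest.approx(0.09 * before, rel=1e-9)

    def test_contamination_never_increases_scores_either_mode(self, rng):
        table = make_cov_table(rng, n_samples=10)
        raw = scores_from_coverage(table)["score"].to_numpy()
        for mode in ("allocate", "uniform_fraction"):
            cfg = ContamSimConfig(max_fraction=0.09, mode=mode, seed=2)
            for it in range(10):
                _, adj = contaminate_once(table, cfg, iteration_seed=it)
                assert np.all(adj["score"].to_numpy() <= raw + 1e-12)

    def test_negative_coverage_rejected(self, rng):
        table = make_cov_table(rng)
        table.loc[1, "mean_coverage"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            contaminate_once(table, ContamSimConfig(), iteration_seed=0)


class TestRunSimulation:
    def test_single_noiseless_iteration_equals_raw_fit(self, rng):
        table = make_cov_table(rng, n_samples=10)
        cfg = ContamSimConfig(max_fraction=0.0, n_iter=1, seed=4)
        result = run_simulation(table, cfg)
        raw_fit = fit_glm(scores_from_coverage(table))
        assert result.headline.F == pytest.approx(raw_fit.F, rel=1e-12)

    def test_default_run_exports_100_iterations(self, rng):
        table = make_cov_table(rng, n_samples=12)
        result = run_simulation(table, ContamSimConfig(seed=4))
        assert len(result.iterations) == 100
        assert list(result.iterations.columns) == ["iteration", "F", "df1", "df2", "p", "r2"]

    def test_same_seed_reproduces_everything(self, rng):
        table = make_cov_table(rng, n_samples=10)
        a = run_simulation(table, ContamSimConfig(n_iter=10, seed=9))
        b = run_simulation(table, ContamSimConfig(n_iter=10, seed=9))
        assert a.iterations.equals(b.iterations)
        assert a.mean_scores.equals(b.mean_scores)


class TestCalibration:
    def test_null_rejection_rate_near_alpha(self):
        # both genera draw scores from the same distribution: the genus
        # F-test should reject at ~5% (99% binomial band over 200 tables)
        rng = np.random.default_rng(77)
        rejections = 0
        n_tables = 200
        for _ in range(n_tables):
            table = score_table(
                {"G": rng.normal(0.1, 0.03, 30), "H": rng.normal(0.1, 0.03, 41)}
            )
            if fit_glm(table).p < 0.05:
                rejections += 1
        import scipy.stats

        lo, hi = scipy.stats.binom.interval(0.99, n_tables, 0.05)
        assert lo <= rejections <= hi

    def test_power_at_preset_effect_size(self):
        # wing alpha U(0.05,0.25) vs body U(0,0.08) translated to scores
        # alpha/(1-alpha): at n=71 the genus test should nearly always reject
        rng = np.random.default_rng(78)
        hits = 0
        for _ in range(50):
            wing = rng.uniform(0.05, 0.25, 30)
            body = rng.uniform(0.0, 0.08, 41)
            table = score_table({"G": wing / (1 - wing), "H": body / (1 - body)})
            if fit_glm(table).p < 0.05:
                hits += 1
        assert hits / 50 > 0.9
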