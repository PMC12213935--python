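"""Association cascade: screening, OLS, RESET, additive model, comparison."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_observations
from sleepvoice.inference import (RankDeficiencyError, ScreeningError,
                                  association_cascade, classify_importances,
                                  compare_models, fit_gam, fit_linear,
                                  reset_test, screen_features)


def synthetic_lm(n, coefs, noise_sd, seed=0, outcome="sleepiness"):
    """Table with a known linear data-generating process."""
    rng = np.random.default_rng(seed)
    cols = {name: rng.normal(size=n) for name in coefs}
    y = sum(b * cols[name] for name, b in coefs.items())
    y = y + noise_sd * rng.standard_normal(n)
    cols[outcome] = y
    return pd.DataFrame(cols)


class TestScreening:
    def test_outcome_copy_ranks_first(self):
        obs = make_observations(n_participants=8, attempts_per_session=6,
                                seed=3)
        obs["leak"] = obs["sleepiness"].astype(float)
        table = screen_features(obs, candidates=("vrt_seconds", "age",
                                                 "caffeine", "leak"),
                                cutoff=0.0, seed=0)
        ranked = max(table.importances, key=table.importances.get)
        assert ranked == "leak"

    def test_cutoff_rule_partition(self):
        t = classify_importances({"a": 120.0, "b": 12.0, "c": 8.0},
                                 cutoff=50.0)
        assert t.retained == ("a",) and set(t.dropped) == {"b", "c"}

    def test_manual_exclusion_separate_from_cutoff(self):
        t = classify_importances({"a": 120.0, "race": 200.0, "b": 10.0},
                                 cutoff=50.0, manual_exclusions=("race",))
        assert "race" in t.manually_excluded
        assert "race" not in t.retained and "race" not in t.dropped
        assert set(t.retained) | set(t.dropped) | set(t.manually_excluded) \
            == {"a", "race", "b"}

    def test_constant_outcome_rejected(self):
        df = pd.DataFrame({"sleepiness": np.ones(50),
                           "x": np.arange(50.0)})
        with pytest.raises(ScreeningError):
            screen_features(df, candidates=("x",))

    def test_planted_coupling_beats_noise_across_seeds(self):
        """A feature genuinely linked to the outcome outranks a pure-noise
        feature in >=95/100 seeded screens."""
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 300
            level = rng.integers(1, 5, n)
            vrt = np.exp(0.39 + 0.4 * (level - 1)
                         + 0.3 * rng.standard_normal(n))
            df = pd.DataFrame({"sleepiness": level, "vrt_seconds": vrt,
                               "noise": rng.standard_normal(n)})
            t = screen_features(df, candidates=("vrt_seconds", "noise"),
                                cutoff=0.0, n_trees=100, seed=seed)
            wins += t.importances["vrt_seconds"] > t.importances["noise"]
        assert wins >= 95


class TestFitLinear:
    def test_noiseless_recovery_to_machine_precision(self):
        coefs = {"vrt_seconds": 0.7, "age": -0.02, "caffeine": 0.3}
        df = synthetic_lm(200, coefs, noise_sd=0.0, seed=1)
        fit = fit_linear(df, tuple(coefs))
        # independent oracle: normal equations via lstsq
        X = np.column_stack([np.ones(200)] + [df[c] for c in coefs])
        beta = np.linalg.lstsq(X, df["sleepiness"], rcond=None)[0]
        got = fit.terms.set_index("term")["estimate"]
        assert got["Intercept"] == pytest.approx(beta[0], abs=1e-8)
        for i, c in enumerate(coefs):
            assert got[c] == pytest.approx(beta[i + 1], abs=1e-8)
            assert got[c] == pytest.approx(coefs[c], abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_outcome_zero_slopes_zero_r2(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"sleepiness": np.full(60, 2.0),
                           "vrt_seconds": rng.normal(size=60)})
        fit = fit_linear(df, ("vrt_seconds",))
        assert fit.terms.set_index("term")["estimate"]["vrt_seconds"] \
            == pytest.approx(0.0, abs=1e-10)
        assert fit.r_squared == 0.0

    def test_variance_decomposition_recovers_r2(self):
        """Noise chosen so var(signal)/var(total) = 0.586 at n=10,000:
        the fitted R^2 lands within 0.02 of it."""
        rng = np.random.default_rng(7)
        n = 10_000
        x = rng.standard_normal(n)
        signal = 1.0 * x
        target = 0.586
        noise_sd = np.sqrt(np.var(signal) * (1 - target) / target)
        df = pd.DataFrame({"vrt_seconds": x,
                           "sleepiness": signal
                           + noise_sd * rng.standard_normal(n)})
        fit = fit_linear(df, ("vrt_seconds",))
        assert fit.r_squared == pytest.approx(target, abs=0.02)

    def test_reference_coding(self):
        obs = make_observations(n_participants=10, attempts_per_session=6,
                                seed=5)
        fit = fit_linear(obs, ("vrt_seconds", "sex", "mood", "bzra_use"))
        terms = set(fit.terms["term"])
        assert "C(sex, Treatment('female'))[T.male]" in terms
        assert "C(mood, Treatment(1))[T.2]" in terms

    def test_rank_deficiency_names_columns(self):
        df = synthetic_lm(100, {"a": 1.0}, noise_sd=0.1, seed=2)
        df["b"] = 2.0 * df["a"]
        with pytest.raises(RankDeficiencyError, match="b"):
            fit_linear(df, ("a", "b"))

    def test_ci_is_est_pm_1p96_se(self):
        df = synthetic_lm(150, {"a": 0.5}, noise_sd=1.0, seed=3)
        fit = fit_linear(df, ("a",))
        row = fit.terms.set_index("term").loc["a"]
        assert row["ci_low"] == pytest.approx(row["estimate"]
                                              - 1.96 * row["se"])
        assert row["ci_high"] == pytest.approx(row["estimate"]
                                               + 1.96 * row["se"])


class TestReset:
    def test_strong_quadratic_truth_detected(self):
        """Quadratic signal at n=500: RESET rejects in >=99/100 seeds."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(500)
            df = pd.DataFrame({"x": x,
                               "sleepiness": x + 0.8 * x**2
                               + 0.5 * rng.standard_normal(500)})
            p = reset_test(fit_linear(df, ("x",)))
            hits += p <= 0.05
        assert hits >= 99

    def test_linear_truth_usually_not_rejected(self):
        rng = np.random.default_rng(42)
        rejected = 0
        for _ in range(50):
            x = rng.standard_normal(300)
            df = pd.DataFrame({"x": x,
                               "sleepiness": 0.5 * x
                               + rng.standard_normal(300)})
            rejected += reset_test(fit_linear(df, ("x",))) <= 0.05
        assert rejected <= 8  # ~5% nominal; generous 3-sigma margin


class TestFitGam:
    def test_linear_truth_shrinks_to_linear(self):
        rng = np.random.default_rng(0)
        n = 800
        df = pd.DataFrame({"vrt_seconds": rng.uniform(0, 5, n),
                           "age": rng.uniform(55, 75, n)})
        df["sleepiness"] = (0.4 * df["vrt_seconds"] - 0.05 * df["age"]
                            + 0.5 * rng.standard_normal(n))
        gam = fit_gam(df, smooth_features=("vrt_seconds", "age"),
                      linear_features=())
        for f, d in gam.smooth_terms.items():
            assert d["edf"] <= 1.5, f

    def test_planted_age_peak_recovered(self):
        """Inverted-U age effect peaking at 64 recovered within 3 years."""
        rng = np.random.default_rng(12)
        n = 1500
        age = rng.uniform(56, 74, n)
        effect = -0.02 * (age - 64.0) ** 2
        y = 2.0 + effect + 0.5 * rng.standard_normal(n)
        df = pd.DataFrame({"age": age, "sleepiness": y})
        gam = fit_gam(df, smooth_features=("age",), linear_features=())
        d = gam.smooth_terms["age"]
        peak = d["x"][np.argmax(d["curve"])]
        assert abs(peak - 64.0) <= 3.0

    def test_monotone_vrt_effect_recovered(self):
        rng = np.random.default_rng(3)
        n = 1200
        vrt = rng.lognormal(0.4, 0.7, n)
        y = 1.5 + 0.25 * np.log1p(vrt) * 2 + 0.4 * rng.standard_normal(n)
        df = pd.DataFrame({"vrt_seconds": vrt, "sleepiness": y})
        gam = fit_gam(df, smooth_features=("vrt_seconds",),
                      linear_features=())
        d = gam.smooth_terms["vrt_seconds"]
        lo, hi = np.percentile(d["x"], [5, 95])
        core = (d["x"] >= lo) & (d["x"] <= hi)
        diffs = np.diff(d["curve"][core])
        assert np.all(diffs >= -1e-6)

    def test_basis_larger_than_unique_values_rejected(self):
        df = pd.DataFrame({"education": np.tile([12, 14, 16, 18], 50),
                           "sleepiness": np.random.default_rng(0)
                           .normal(size=200)})
        with pytest.raises(ValueError, match="basis size"):
            fit_gam(df, smooth_features=("education",), linear_features=(),
                    k=10)


class TestCompareModels:
    def test_nested_equivalence_aic_close(self):
        obs = make_observations(n_participants=10, attempts_per_session=8,
                                seed=21)
        feats = ("vrt_seconds", "age", "caffeine")
        lin = fit_linear(obs, feats)
        gam = fit_gam(obs, smooth_features=(), linear_features=feats)
        assert abs(lin.aic - gam.aic) < 2.0
        cmp = compare_models(lin, gam)
        assert abs(cmp.delta_aic) < 2.0

    def test_planted_nonlinearity_prefers_gam(self):
        rng = np.random.default_rng(5)
        n = 1000
        vrt = rng.uniform(0, 6, n)
        df = pd.DataFrame({"vrt_seconds": vrt,
                           "sleepiness": np.sin(vrt) * 1.2
                           + 0.5 * rng.standard_normal(n)})
        lin = fit_linear(df, ("vrt_seconds",))
        gam = fit_gam(df, smooth_features=("vrt_seconds",),
                      linear_features=())
        cmp = compare_models(lin, gam)
        assert gam.aic < lin.aic
        assert cmp.winner == "additive model"
        assert cmp.anova_p < 0.01

    def test_differing_rows_rejected(self):
        df = synthetic_lm(100, {"a": 1.0}, noise_sd=0.5)
        lin = fit_linear(df, ("a",))
        lin2 = fit_linear(df.iloc[:80], ("a",))
        with pytest.raises(ValueError, match="row counts"):
            compare_models(lin, fit_gam(df.iloc[:80], (), ("a",)))
        assert lin2.n == 80


class TestCascade:
    def test_branch_fidelity_nonlinear_world(self):
        """Lognormal VRT link world: RESET rejects, the additive model is
        fitted and compared."""
        obs = make_observations(n_participants=12, attempts_per_session=10,
                                seed=8, slope=0.3, noise_sd=0.4)
        res = association_cascade(obs, screening_cutoff=0.0, n_trees=100,
                                  seed=0)
        assert res.reset_p <= 0.05
        assert res.gam is not None and res.comparison is not None

    def test_null_vrt_smooth_rarely_significant(self):
        """With zero planted coupling the VRT smooth's p-value should be
        non-significant in >=90/100 seeded worlds."""
        calm = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 400
            df = pd.DataFrame({
                "vrt_seconds": rng.lognormal(0.4, 0.7, n),
                "sleepiness": rng.integers(1, 5, n).astype(float)})
            gam = fit_gam(df, smooth_features=("vrt_seconds",),
                          linear_features=())
            calm += gam.smooth_terms["vrt_seconds"]["p_value"] > 0.05
        assert calm >= 90
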