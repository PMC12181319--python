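"""Outlier rules, OLS against a normal-equations oracle, Holm, effect sizes
and JZS Bayes factors."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy import stats as sps

import cogbattery as cb
from cogbattery.inference import (
    CollinearityError,
    InsufficientDataError,
    ModelSpec,
    simulate_null_analysis_table,
)


class TestTukey:
    def test_quartile_oracle(self):
        x = np.concatenate([np.arange(1, 101), [1000]])
        mask = cb.tukey_outlier_mask(x)
        assert mask.sum() == 1 and mask[-1]

    def test_no_extremes(self):
        assert not cb.tukey_outlier_mask(np.linspace(-1, 1, 50)).any()

    def test_constant_vector(self):
        assert not cb.tukey_outlier_mask(np.ones(10)).any()

    def test_needs_four_values(self):
        with pytest.raises(ValueError):
            cb.tukey_outlier_mask([1.0, 2.0, 3.0])


class TestGroupwise2SD:
    def test_normal_tail_fraction(self, rng):
        x = rng.normal(size=20_000)
        g = np.repeat(["a", "b"], 10_000)
        frac = cb.groupwise_2sd_mask(x, g).mean()
        assert frac == pytest.approx(0.0455, abs=0.006)

    def test_all_equal_none_flagged(self):
        assert not cb.groupwise_2sd_mask([1.0] * 6, ["a"] * 3 + ["b"] * 3).any()

    def test_groups_independent(self):
        x = np.array([0.0, 0.1, -0.1, 100.0, 0.0, 0.1, -0.1])
        g = np.array(["a", "a", "a", "a", "b", "b", "b"])
        mask = cb.groupwise_2sd_mask(x, g)
        assert not mask[g == "b"].any()

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            cb.groupwise_2sd_mask([1.0, 2.0, 3.0], ["a", "a", "b"])


def _ols_oracle(X, y):
    """Normal equations: b, SE, t for a design with intercept."""
    XtX_inv = np.linalg.inv(X.T @ X)
    b = XtX_inv @ X.T @ y
    resid = y - X @ b
    n, p = X.shape
    s2 = resid @ resid / (n - p)
    se = np.sqrt(np.diag(XtX_inv) * s2)
    return b, se, b / se


class TestLinearModel:
    def test_matches_normal_equations_oracle(self, rng):
        """b/SE/beta/t match brute-force linear algebra on random designs."""
        for _ in range(100):
            n = int(rng.integers(15, 50))
            p = int(rng.integers(1, 6))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            data = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)])
            data["y"] = y
            spec = ModelSpec(outcome="y", focal="x0",
                             covariates=tuple(f"x{j}" for j in range(1, p)))
            res = cb.fit_linear_model(data, spec, compute_bf=False)
            Xd = np.column_stack([np.ones(n), X])
            b, se, t = _ols_oracle(Xd, y)
            for j, term in enumerate(spec.terms(), start=1):
                st = res.terms[term]
                assert st.b == pytest.approx(b[j], rel=1e-8, abs=1e-10)
                assert st.se == pytest.approx(se[j], rel=1e-8, abs=1e-10)
                assert st.t == pytest.approx(t[j], rel=1e-8, abs=1e-10)
                beta = b[j] * np.std(X[:, j - 1], ddof=1) / np.std(y, ddof=1)
                assert st.beta == pytest.approx(beta, rel=1e-8)

    def test_noiseless_limit(self, rng):
        x = rng.normal(size=200)
        data = pd.DataFrame({"x": x, "y": 2 * x + rng.normal(0, 1e-8, 200)})
        res = cb.fit_linear_model(
            data, ModelSpec(outcome="y", focal="x", covariates=()), compute_bf=False
        )
        assert res.terms["x"].b == pytest.approx(2.0, abs=1e-6)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)

    def test_age_centered_within_sample(self, rng):
        n = 120
        data = pd.DataFrame({
            "age": rng.normal(50, 10, n),
            "y": rng.normal(size=n),
        })
        res = cb.fit_linear_model(
            data, ModelSpec(outcome="y", focal="age", covariates=()),
            compute_bf=False,
        )
        # with centered age the intercept equals the sample mean of y
        assert res.intercept.b == pytest.approx(float(data["y"].mean()), abs=1e-10)

    def test_collinearity_named(self, rng):
        x = rng.normal(size=40)
        data = pd.DataFrame({"x1": x, "x2": 2 * x, "y": rng.normal(size=40)})
        with pytest.raises(CollinearityError):
            cb.fit_linear_model(
                data, ModelSpec(outcome="y", focal="x1", covariates=("x2",)),
                compute_bf=False,
            )

    def test_insufficient_data(self, rng):
        data = pd.DataFrame({"x": [1.0, 2.0], "y": [0.1, 0.2]})
        with pytest.raises(InsufficientDataError):
            cb.fit_linear_model(
                data, ModelSpec(outcome="y", focal="x", covariates=()),
                compute_bf=False,
            )

    def test_permuted_outcome_p_uniform(self):
        """Focal p under permuted outcomes is Uniform(0,1) (KS over reps)."""
        rng = np.random.default_rng(77)
        ps = []
        spec = ModelSpec(outcome="outcome", focal="infection")
        data = simulate_null_analysis_table(120, rng)
        for _ in range(300):
            shuffled = data.copy()
            shuffled["outcome"] = rng.permutation(shuffled["outcome"].to_numpy())
            res = cb.fit_linear_model(shuffled, spec, compute_bf=False)
            ps.append(res.terms["infection"].p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_focal_power_exceeds_alpha_at_study_group_sizes():
    """With a real deficit the focal test rejects far above the 5% rate."""
    from cogbattery.inference import focal_power_simulation

    power = focal_power_simulation(n_reps=300, seed=21)
    assert power > 0.5


class TestHolm:
    def test_single_p_unchanged(self):
        assert cb.holm_adjust([0.03])[0] == 0.03

    def test_hand_stepdown(self):
        np.testing.assert_allclose(cb.holm_adjust([0.01, 0.04]), [0.02, 0.04])
        np.testing.assert_allclose(cb.holm_adjust([0.05] * 4), [0.2] * 4)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0.001, 1.0, size=12)
        mine = cb.holm_adjust(p)
        _, theirs, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(mine, theirs, atol=1e-12)

    def test_permutation_invariant(self, rng):
        p = rng.uniform(0.001, 1.0, size=9)
        perm = rng.permutation(9)
        np.testing.assert_allclose(cb.holm_adjust(p)[perm], cb.holm_adjust(p[perm]))

    def test_adjusted_at_least_raw_and_capped(self, rng):
        p = rng.uniform(0.001, 1.0, size=20)
        adj = cb.holm_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()


class TestEffectSizeAndTTests:
    def test_equal_means_zero(self):
        assert cb.cohens_d_pooled(1.0, 1.0, 10, 1.0, 2.0, 10) == 0.0

    def test_unit_pooled_sd(self):
        assert cb.cohens_d_pooled(1.0, 1.0, 10, 0.0, 1.0, 10) == pytest.approx(1.0)

    def test_group_descriptives_formula(self):
        """LDI group descriptives give d of about -0.45."""
        d = cb.cohens_d_pooled(0.24, 0.17, 76, 0.32, 0.19, 62)
        assert d == pytest.approx(-0.446, abs=0.005)

    def test_identical_groups_t_zero(self):
        x = np.arange(10.0)
        t, df, p = cb.welch_or_student_ttest(x, x)
        assert t == 0.0 and df == 18 and p == 1.0

    def test_hand_computed_3v3(self):
        x, y = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        t, df, p = cb.welch_or_student_ttest(x, y)
        # pooled s2 = (2*1 + 2*4)/4 = 2.5 -> t = -2 / sqrt(2.5 * 2/3)
        assert df == 4
        assert t == pytest.approx(-2.0 / math.sqrt(2.5 * 2 / 3), abs=1e-12)

    def test_null_type_one_rate(self, rng):
        hits = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(size=25)
            y = rng.normal(size=25)
            _, _, p = cb.welch_or_student_ttest(x, y)
            hits += p < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.03)


def _bf_g_integral_oracle(t, n1, n2, r=math.sqrt(2) / 2):
    """Independent quadrature oracle: mixture-of-g form of the JZS BF
    (marginalizing g ~ InverseGamma(1/2, r^2/2) over the g-prior likelihood
    ratio) — a different derivation route than the package's noncentral-t
    integral."""
    n_eff = n1 * n2 / (n1 + n2)
    nu = n1 + n2 - 2

    def ig_pdf(g):
        a, b = 0.5, r**2 / 2
        return b**a / math.gamma(a) * g ** (-a - 1) * math.exp(-b / g)

    def integrand(g):
        return (
            (1 + n_eff * g) ** -0.5
            * (1 + t**2 / ((1 + n_eff * g) * nu)) ** (-(nu + 1) / 2)
            * ig_pdf(g)
        )

    numerator, _ = integrate.quad(integrand, 0, np.inf, limit=300)
    denominator = (1 + t**2 / nu) ** (-(nu + 1) / 2)
    return numerator / denominator


class TestBayesFactors:
    def test_zero_t_favors_null(self):
        assert cb.bf10_ttest(0.0, 50, 50) < 1.0

    def test_monotone_in_abs_t(self):
        bfs = [cb.bf10_ttest(t, 30, 30) for t in (0.0, 0.5, 1.0, 2.0, 3.0, 5.0)]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))
        assert cb.bf10_ttest(-2.5, 30, 30) == pytest.approx(
            cb.bf10_ttest(2.5, 30, 30), rel=1e-6
        )

    @pytest.mark.parametrize("t, n", [(2.5, 40), (0.8, 25), (4.0, 60), (-1.7, 33)])
    def test_matches_g_integral_oracle(self, t, n):
        mine = cb.bf10_ttest(t, n, n)
        oracle = _bf_g_integral_oracle(t, n, n)
        assert mine == pytest.approx(oracle, rel=1e-3)  # 3 significant figures

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        mine = cb.bf10_ttest(2.5, 40, 40)
        theirs = float(pingouin.bayesfactor_ttest(2.5, 40, 40))
        assert mine == pytest.approx(theirs, rel=1e-3)

    def test_regression_bf_null_concentrates_below_one(self):
        rng = np.random.default_rng(5)
        bfs = []
        spec = ModelSpec(outcome="outcome", focal="infection")
        for _ in range(20):
            data = simulate_null_analysis_table(400, rng)
            bfs.append(cb.bf10_regression_term(data, spec, "infection"))
        assert np.median(bfs) < 1.0

    def test_regression_bf_large_effect(self):
        rng = np.random.default_rng(6)
        n = 500
        x = rng.normal(size=n)
        data = pd.DataFrame({
            "x": x,
            "z": rng.normal(size=n),
            "y": 0.5 * x + rng.normal(0, np.sqrt(1 - 0.25), n),
        })
        spec = ModelSpec(outcome="y", focal="x", covariates=("z",))
        assert cb.bf10_regression_term(data, spec, "x") > 10

    def test_empty_focal_is_identity(self):
        rng = np.random.default_rng(7)
        data = pd.DataFrame({"x": rng.normal(size=50), "y": rng.normal(size=50)})
        spec = ModelSpec(outcome="y", focal=None, covariates=("x",))
        assert cb.bf10_regression_term(data, spec, None) == 1.0


class TestInterpretBf:
    @pytest.mark.parametrize(
        "bf, band",
        [
            (12.0, "strong_H1"),
            (10.0 + 1e-9, "strong_H1"),
            (5.0, "moderate_H1"),
            (2.0, "anecdotal_H1"),
            (1.0, "equivocal"),
            (0.5, "anecdotal_H0"),
            (1 / 3, "anecdotal_H0"),
            (0.2, "moderate_H0"),
            (0.1, "moderate_H0"),
            (0.05, "strong_H0"),
        ],
    )
    def test_bands(self, bf, band):
        assert cb.interpret_bf(bf) == band

    def test_invalid(self):
        with pytest.raises(ValueError):
            cb.interpret_bf(0.0)
        with pytest.raises(ValueError):
            cb.interpret_bf(float("nan"))
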