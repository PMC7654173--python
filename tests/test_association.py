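"""Univariable logistic screens, PRS association, LRT interactions and
Spearman independence."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import polyrisk as pr
from polyrisk.errors import DegenerateInputError

from conftest import encoded_cohort


def two_by_two_frame(exp_cases, exp_controls, unexp_cases, unexp_controls):
    n = exp_cases + exp_controls + unexp_cases + unexp_controls
    outcome = [1] * exp_cases + [0] * exp_controls + [1] * unexp_cases + [0] * unexp_controls
    exposed = [1.0] * (exp_cases + exp_controls) + [0.0] * (unexp_cases + unexp_controls)
    return pd.DataFrame({"outcome": outcome, "exposed": exposed},
                        index=pd.RangeIndex(n))


class TestUnivariableFit:
    def test_two_by_two_matches_cross_product_oracle(self):
        df = two_by_two_frame(30, 20, 70, 80)
        fit = pr.univariable_fit(df, "exposed", covariates=())
        oracle = (30 * 80) / (70 * 20)
        assert fit.or_per_unit == pytest.approx(oracle, abs=1e-6)
        assert fit.ci_low < oracle < fit.ci_high

    def test_null_factor_or_near_one(self):
        rng = np.random.default_rng(0)
        n = 5000
        df = pd.DataFrame({
            "outcome": rng.binomial(1, 0.4, n),
            "x": rng.normal(size=n),
            "age_bin": rng.integers(0, 8, n).astype(float),
            "centre": rng.choice(["centre_1", "centre_2"], n),
        })
        fit = pr.univariable_fit(df, "x")
        assert 0.9 < fit.or_per_unit < 1.1

    def test_recovers_true_effect_with_nominal_coverage(self):
        true_beta = 0.5
        covered = 0
        reps = 50
        for rep in range(reps):
            rng = np.random.default_rng(3000 + rep)
            n = 20_000
            x = rng.normal(size=n)
            y = rng.binomial(1, expit(-1.0 + true_beta * x))
            df = pd.DataFrame({"outcome": y, "x": x})
            fit = pr.univariable_fit(df, "x", covariates=())
            covered += fit.ci_low <= math.exp(true_beta) <= fit.ci_high
        assert covered / reps >= 0.90

    def test_standardized_beta_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(5)
        n = 2000
        x = rng.normal(size=n)
        y = rng.binomial(1, expit(0.4 * x))
        df = pd.DataFrame({"outcome": y, "x": x, "x_scaled": 3.0 * x + 7.0})
        a = pr.univariable_fit(df, "x", covariates=())
        b = pr.univariable_fit(df, "x_scaled", covariates=())
        assert a.std_beta == pytest.approx(b.std_beta, rel=1e-6)

    def test_constant_factor_rejected(self):
        df = two_by_two_frame(5, 5, 5, 5)
        df["exposed"] = 1.0
        with pytest.raises(DegenerateInputError):
            pr.univariable_fit(df, "exposed", covariates=())


class TestPrsAssociation:
    def test_null_prs_or_near_one_and_tail_contrasts_reported(self):
        rng = np.random.default_rng(6)
        n = 4000
        df = pd.DataFrame({
            "outcome": rng.binomial(1, 0.4, n),
            "age_bin": rng.integers(0, 8, n).astype(float),
        })
        score = pd.Series(rng.normal(size=n), index=df.index)
        fit = pr.prs_association(df, score)
        assert 0.9 < fit.or_per_unit < 1.1
        tails = fit.extra["tail_contrasts"]
        assert set(tails) == {"bottom", "top"}
        assert 0.5 < tails["top"]["or"] < 2.0

    def test_recovers_generative_per_sd_effect(self):
        target = math.log(1.5)
        covered = 0
        reps = 40
        for rep in range(reps):
            rng = np.random.default_rng(4000 + rep)
            n = 6000
            score = rng.normal(size=n)
            y = rng.binomial(1, expit(-0.5 + target * score))
            df = pd.DataFrame({"outcome": y,
                               "age_bin": rng.integers(0, 8, n).astype(float)})
            fit = pr.prs_association(df, pd.Series(score, index=df.index))
            covered += fit.ci_low <= 1.5 <= fit.ci_high
        assert covered / reps >= 0.90


class TestInteractionLrt:
    def _frame(self, n, inter_coef, seed):
        rng = np.random.default_rng(seed)
        age = rng.integers(0, 8, n).astype(float)
        dens = rng.choice([1.0, 1.3, 1.8, 2.2, 3.0], n)
        lp = -1.0 + 0.05 * age + 0.3 * np.log(dens) + inter_coef * age * dens
        lp -= lp.mean()
        return pd.DataFrame({
            "outcome": rng.binomial(1, expit(lp)),
            "age_bin": age,
            "density_enc": dens,
            "centre": rng.choice(["centre_1", "centre_2"], n),
        })

    def test_strong_interaction_detected(self):
        hits = 0
        reps = 15
        for rep in range(reps):
            res = pr.interaction_lrt(self._frame(5000, 0.5, 5000 + rep),
                                     "age", "density_enc")
            hits += res["p"] < 0.01
        assert hits >= 14  # >= 95% power at this effect and n

    def test_constant_interaction_column_gives_zero(self):
        df = self._frame(200, 0.0, 1)
        df["density_enc"] = 1.0  # product == age, collinear with main effect
        res = pr.interaction_lrt(df, "age", "density_enc")
        assert res["lrt"] == 0.0 and res["p"] == 1.0

    def test_lrt_nonnegative(self):
        for rep in range(5):
            res = pr.interaction_lrt(self._frame(400, 0.0, rep), "age", "density_enc")
            assert res["lrt"] >= 0.0


class TestSpearmanIndependence:
    def test_self_correlation_and_rank_invariance(self, study_cohort):
        _, cohort = study_cohort
        df = cohort.phenotypes.copy()
        df["prs_monotone"] = np.exp(df["prs_std"])
        rho, _ = pr.spearman_independence(df, ["prs_std", "prs_monotone"])
        assert rho.loc["prs_std", "prs_std"] == 1.0
        assert rho.loc["prs_std", "prs_monotone"] == pytest.approx(1.0)

    def test_independent_prs_and_density_uncorrelated(self):
        hits = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(6000 + rep)
            n = 642
            df = pd.DataFrame({
                "outcome": np.zeros(n, dtype=int),
                "prs_std": rng.normal(size=n),
                "density_enc": rng.choice([1.0, 1.3, 1.8, 2.2, 3.0], n),
            })
            rho, _ = pr.spearman_independence(df, ["prs_std", "density_enc"])
            hits += abs(rho.loc["prs_std", "density_enc"]) < 0.1
        assert hits >= 19

    def test_constant_variable_reported_as_nan(self):
        df = pd.DataFrame({"outcome": [0, 0, 0, 0],
                           "a": [1.0, 2.0, 3.0, 4.0],
                           "b": [2.0, 2.0, 2.0, 2.0]})
        rho, _ = pr.spearman_independence(df, ["a", "b"])
        assert np.isnan(rho.loc["a", "b"])

    def test_requires_three_controls(self):
        df = pd.DataFrame({"outcome": [1, 1, 0], "a": [1.0, 2.0, 3.0]})
        with pytest.raises(DegenerateInputError):
            pr.spearman_independence(df, ["a"])
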