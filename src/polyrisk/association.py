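"""Univariable association screens, PRS association and interaction tests.

Every phenotype factor is screened by a logistic regression of case status
on its quantitative (OR-encoded) value, adjusted for age bin and centre;
the PRS is fitted on its standardized scale adjusted for age bin and the
first five genotype principal components. Interactions are assessed by the
likelihood ratio test between nested fits, and independence between the
PRS and the phenotype factors by pairwise Spearman correlations over the
unaffected controls.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._logistic import fit_logit, wald_summary
from .data import Cohort, PRSResult
from .errors import ConfigurationError, DegenerateInputError

#: p-value threshold used for variable selection throughout (two-sided).
SIGNIFICANCE_THRESHOLD = 0.05


@dataclass
class FitResult:
    """One association fit: OR per unit of the predictor with Wald CI and p,
    plus the post-hoc standardized coefficient (beta x SD of predictor)."""

    factor: str
    or_per_unit: float
    ci_low: float
    ci_high: float
    p_value: float
    std_beta: float
    n: int
    covariates: tuple = ()
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_THRESHOLD

    def row(self) -> dict:
        return {"factor": self.factor, "or": self.or_per_unit,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "p": self.p_value, "std_beta": self.std_beta, "n": self.n}


def _centre_dummies(centre: pd.Series) -> pd.DataFrame:
    d = pd.get_dummies(centre, prefix="centre", drop_first=True, dtype=float)
    return d


def _design(df: pd.DataFrame, main: str, covariates) -> pd.DataFrame:
    X = pd.DataFrame({"const": 1.0, main: df[main].astype(float)}, index=df.index)
    for cov in covariates:
        if cov == "centre":
            X = pd.concat([X, _centre_dummies(df["centre"])], axis=1)
        else:
            X[cov] = df[cov].astype(float)
    return X


def univariable_fit(cohort: Cohort | pd.DataFrame, factor: str,
                    covariates: tuple = ("age_bin", "centre")) -> FitResult:
    """Logistic regression of case status on one encoded factor, adjusted
    for age bin and centre."""
    df = cohort.phenotypes if isinstance(cohort, Cohort) else cohort
    col = factor if factor in df.columns else f"{factor}_enc"
    if col not in df.columns:
        raise ConfigurationError(f"factor '{factor}' has no encoded column in the cohort")
    vals = df[col].astype(float)
    if vals.nunique() < 2:
        raise DegenerateInputError(f"factor '{factor}' is constant; no association fit")
    X = _design(df, col, covariates)
    res = fit_logit(X, df["outcome"])
    orv, lo, hi, p = wald_summary(res, col)
    return FitResult(factor, orv, lo, hi, p,
                     std_beta=float(res.params[col]) * float(vals.std(ddof=1)),
                     n=len(df), covariates=tuple(covariates))


def prs_association(cohort: Cohort | pd.DataFrame, prs: PRSResult | pd.Series,
                    pcs: pd.DataFrame | None = None,
                    adjust_centre: bool = False,
                    tail: float = 0.05,
                    reference: tuple = (0.40, 0.60)) -> FitResult:
    """Association of the standardized PRS with case status.

    Fits ``outcome ~ PRS_std + age_bin + PC1..PCk`` (centre optionally added
    via ``adjust_centre``). The result's ``extra`` carries two tail
    contrasts — the bottom and top ``tail`` fraction of the PRS
    distribution, each against the middle ``reference`` band — estimated by
    indicator logistic regression.
    """
    df = (cohort.phenotypes if isinstance(cohort, Cohort) else cohort).copy()
    score = prs.standardized if isinstance(prs, PRSResult) else prs
    df["prs_std"] = score.loc[df.index].astype(float)
    covs = ["age_bin"] + (["centre"] if adjust_centre else [])
    X = _design(df, "prs_std", covs)
    if pcs is not None:
        X = pd.concat([X, pcs.loc[df.index].astype(float)], axis=1)
    res = fit_logit(X, df["outcome"])
    orv, lo, hi, p = wald_summary(res, "prs_std")

    extra = {"tail_contrasts": _tail_contrasts(df["prs_std"], df["outcome"],
                                               tail, reference)}
    return FitResult("prs", orv, lo, hi, p,
                     std_beta=float(res.params["prs_std"]),
                     n=len(df),
                     covariates=tuple(covs) + (tuple(pcs.columns) if pcs is not None else ()),
                     extra=extra)


def _tail_contrasts(score: pd.Series, outcome: pd.Series, tail, reference):
    qs = score.quantile([tail, reference[0], reference[1], 1 - tail])
    bands = {
        "bottom": score <= qs.iloc[0],
        "reference": (score > qs.iloc[1]) & (score <= qs.iloc[2]),
        "top": score > qs.iloc[3],
    }
    out = {}
    for which in ("bottom", "top"):
        sel = bands[which] | bands["reference"]
        X = pd.DataFrame({"const": 1.0, "band": bands[which].astype(float)})[sel.to_numpy()]
        y = outcome[sel]
        try:
            res = fit_logit(X, y)
            orv, lo, hi, p = wald_summary(res, "band")
            out[which] = {"or": orv, "ci_low": lo, "ci_high": hi, "p": p}
        except Exception as exc:  # sparse tails can separate at small n
            out[which] = {"or": float("nan"), "error": str(exc)}
    return out


def interaction_lrt(cohort: Cohort | pd.DataFrame, factor_a: str, factor_b: str,
                    covariates: tuple = ("age_bin", "centre")) -> dict:
    """Likelihood ratio test for an a x b interaction on top of both main
    effects (plus covariates): LRT = 2(ll_full - ll_reduced) ~ chi2(1).

    ``"age"`` may be used as a factor name; its value is the age-bin index.
    """
    df = cohort.phenotypes if isinstance(cohort, Cohort) else cohort

    def col(f):
        if f == "age":
            return df["age_bin"].astype(float)
        c = f if f in df.columns else f"{f}_enc"
        if c not in df.columns:
            raise ConfigurationError(f"factor '{f}' has no encoded column in the cohort")
        return df[c].astype(float)

    va, vb = col(factor_a), col(factor_b)
    X = pd.DataFrame({"const": 1.0, "a": va, "b": vb}, index=df.index)
    for cov in covariates:
        if cov == "centre":
            X = pd.concat([X, _centre_dummies(df["centre"])], axis=1)
        elif cov == "age_bin" and "age" in (factor_a, factor_b):
            continue  # age already enters as a main effect
        else:
            X[cov] = df[cov].astype(float)
    product = va * vb
    if product.nunique() < 2 or np.linalg.matrix_rank(
            np.column_stack([X.to_numpy(float), product])) <= X.shape[1]:
        # interaction column adds nothing; the models coincide
        return {"lrt": 0.0, "df": 1, "p": 1.0, "factors": (factor_a, factor_b)}
    reduced = fit_logit(X, df["outcome"])
    Xf = X.copy()
    Xf["a:b"] = product
    full = fit_logit(Xf, df["outcome"])
    lrt = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(stats.chi2.sf(lrt, df=1))
    return {"lrt": float(lrt), "df": 1, "p": p, "factors": (factor_a, factor_b)}


def spearman_independence(cohort: Cohort | pd.DataFrame,
                          variables: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlations over the unaffected controls.

    Returns (rho, p) matrices; pairs involving a constant variable are
    reported as NaN. Requires >= 3 controls.
    """
    df = cohort.phenotypes if isinstance(cohort, Cohort) else cohort
    controls = df[df["outcome"] == 0]
    if len(controls) < 3:
        raise DegenerateInputError("Spearman independence needs >= 3 controls")
    cols = []
    for v in variables:
        c = v if v in controls.columns else f"{v}_enc"
        if c not in controls.columns:
            raise ConfigurationError(f"variable '{v}' not found in cohort")
        cols.append(c)
    data = controls[cols].astype(float)
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    pval = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = data.iloc[:, i], data.iloc[:, j]
            if xi.nunique() < 2 or xj.nunique() < 2:
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(xi, xj)
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pval.iloc[i, j] = pval.iloc[j, i] = p
    for i in range(k):
        if data.iloc[:, i].nunique() < 2:
            rho.iloc[i, i] = np.nan
    return rho, pval
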