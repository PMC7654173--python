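"""The multivariable logistic risk model with interaction terms.

The final model regresses case status on the selected OR-encoded phenotype
factors, the standardized PRS, interaction products (by default age x
density and age x menopause, with age as the ordinal bin index), the age
bin and the recruitment centre. Significance is summarised by per-term and
global Wald tests; calibration by the Hosmer-Lemeshow decile test. The
predicted ``individual risk factor`` is the fitted probability — in a
case-control cohort a *relative* score whose intercept reflects
ascertainment, not an absolute 5-year risk.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from ._logistic import fit_logit
from .data import Cohort
from .errors import ConfigurationError

#: factors forced into the final model irrespective of univariable screening
DEFAULT_FORCED = ("family", "menarche")
DEFAULT_INTERACTIONS = (("age", "density"), ("age", "menopause"))


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the multivariable model.

    ``factors`` are the main-effect names ("prs", phenotype factor names, or
    raw column names); ``interactions`` are pairs of factor names (the
    special name "age" resolves to the age-bin index); ``covariates``
    default to age bin and centre.
    """

    factors: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()
    covariates: tuple[str, ...] = ("age_bin", "centre")

    def __post_init__(self):
        available = set(self.factors) | {"age"}
        for a, b in self.interactions:
            if a not in available or b not in available:
                raise ConfigurationError(
                    f"interaction ({a}, {b}) references a factor not in the model "
                    f"main effects")

    def without_interactions(self) -> "ModelSpec":
        return ModelSpec(self.factors, (), self.covariates)


@dataclass
class RiskModelFit:
    """A fitted multivariable model plus the pieces needed for prediction
    and reporting."""

    spec: ModelSpec
    params: pd.Series
    cov_params: pd.DataFrame
    llf: float
    wald_per_term: pd.DataFrame
    wald_global: dict
    n: int
    converged: bool
    column_names: tuple[str, ...]

    def to_json(self, path) -> None:
        payload = {
            "spec": {"factors": list(self.spec.factors),
                     "interactions": [list(t) for t in self.spec.interactions],
                     "covariates": list(self.spec.covariates)},
            "params": self.params.to_dict(),
            "cov_params": self.cov_params.to_dict(),
            "llf": self.llf,
            "wald_global": self.wald_global,
            "n": self.n,
            "converged": self.converged,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _resolve(df: pd.DataFrame, name: str) -> pd.Series:
    if name == "age":
        col = "age_bin"
    elif name == "prs":
        col = "prs_std"
    elif name in df.columns:
        col = name
    else:
        col = f"{name}_enc"
    if col not in df.columns:
        raise ConfigurationError(f"model term '{name}' resolves to missing column '{col}'")
    return df[col].astype(float)


def build_design(cohort: Cohort | pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Assemble the design matrix: intercept, main effects, interaction
    products, then covariates, in a deterministic order."""
    df = cohort.phenotypes if isinstance(cohort, Cohort) else cohort
    X = pd.DataFrame({"const": 1.0}, index=df.index)
    for f in spec.factors:
        X[f] = _resolve(df, f)
    for a, b in spec.interactions:
        X[f"{a}:{b}"] = _resolve(df, a) * _resolve(df, b)
    for cov in spec.covariates:
        if cov == "centre":
            dummies = pd.get_dummies(df["centre"], prefix="centre",
                                     drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
        elif cov == "age_bin" and "age" in spec.factors:
            continue  # age already a main effect
        else:
            X[cov] = df[cov].astype(float)
    return X


def fit_multivariable(design: pd.DataFrame, outcome) -> RiskModelFit:
    """ML logistic fit with per-term and global Wald tests.

    The global test is the Wald chi-square that all non-intercept
    coefficients are zero.
    """
    res = fit_logit(design, outcome)
    terms = [c for c in design.columns if c != "const"]
    per_term = pd.DataFrame({
        "coef": res.params[terms],
        "se": res.bse[terms],
        "z": res.params[terms] / res.bse[terms],
        "p": res.pvalues[terms],
        "or": np.exp(res.params[terms]),
    })
    b = res.params[terms].to_numpy()
    V = res.cov_params().loc[terms, terms].to_numpy()
    stat = float(b @ np.linalg.solve(V, b))
    wald_global = {"chi2": stat, "df": len(terms),
                   "p": float(stats.chi2.sf(stat, df=len(terms)))}
    return RiskModelFit(
        spec=ModelSpec(tuple(terms)),  # placeholder; callers overwrite via fit_model
        params=res.params.copy(),
        cov_params=res.cov_params().copy(),
        llf=float(res.llf),
        wald_per_term=per_term,
        wald_global=wald_global,
        n=int(design.shape[0]),
        converged=bool(res.mle_retvals.get("converged", False)),
        column_names=tuple(design.columns),
    )


def fit_model(cohort: Cohort | pd.DataFrame, spec: ModelSpec) -> RiskModelFit:
    """Build the design from ``spec`` and fit; the returned fit remembers the
    spec so :func:`predict_risk` can rebuild the design on new cohorts."""
    df = cohort.phenotypes if isinstance(cohort, Cohort) else cohort
    design = build_design(df, spec)
    fit = fit_multivariable(design, df["outcome"])
    fit.spec = spec
    return fit


def predict_risk(fit: RiskModelFit, cohort: Cohort | pd.DataFrame) -> pd.DataFrame:
    """Linear predictor and fitted probability per woman.

    The probability is a relative case-control risk score (the intercept
    absorbs the ascertainment ratio); downstream stratification is
    rank-based and unaffected by that convention.
    """
    df = cohort.phenotypes if isinstance(cohort, Cohort) else cohort
    X = build_design(df, fit.spec)
    missing = [c for c in fit.column_names if c not in X.columns]
    if missing:
        raise ConfigurationError(f"cohort lacks model columns: {missing}")
    X = X[list(fit.column_names)]
    eta = X.to_numpy(float) @ fit.params[list(fit.column_names)].to_numpy()
    return pd.DataFrame({"linear_predictor": eta, "probability": expit(eta)},
                        index=df.index)


def hosmer_lemeshow(probabilities, outcome, groups: int = 10) -> dict:
    """Hosmer-Lemeshow goodness-of-fit chi-square over predicted-risk groups.

    Women are grouped by deciles (or ``groups``-tiles) of predicted
    probability, ties going to the lower group; the statistic sums
    (observed - expected)^2 / expected over groups for both outcomes, with
    ``groups - 2`` degrees of freedom. Groups emptied by ties are merged
    into their lower neighbour with a warning.
    """
    if groups < 3:
        raise ConfigurationError("Hosmer-Lemeshow needs >= 3 groups")
    p = np.asarray(probabilities, float)
    y = np.asarray(outcome, float)
    edges = np.quantile(p, np.linspace(0, 1, groups + 1)[1:-1])
    gidx = np.searchsorted(edges, p, side="left")
    labels = np.unique(gidx)
    if len(labels) < groups:
        warnings.warn(f"ties collapsed {groups - len(labels)} Hosmer-Lemeshow "
                      f"group(s); merged into lower neighbours", stacklevel=2)
    stat = 0.0
    used = 0
    for g in labels:
        sel = gidx == g
        if not sel.any():
            continue
        obs1 = y[sel].sum()
        exp1 = p[sel].sum()
        obs0 = (~(y[sel] == 1)).sum()
        exp0 = sel.sum() - exp1
        if exp1 <= 0 or exp0 <= 0:
            warnings.warn("degenerate expected count in a Hosmer-Lemeshow group; "
                          "group skipped", stacklevel=2)
            continue
        stat += (obs1 - exp1) ** 2 / exp1 + (obs0 - exp0) ** 2 / exp0
        used += 1
    df = max(1, used - 2)
    return {"statistic": float(stat), "df": int(df),
            "p": float(stats.chi2.sf(stat, df=df)), "groups_used": int(used)}
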