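"""Discrimination and risk stratification.

AUC is the Mann-Whitney probability that a random case scores above a
random control (ties credited 1/2). Its sampling distribution is assessed
by repeated random 90/10 train/test splits (refit on each training set),
summarised by the median and percentile 95% interval. Stratification cuts
the cohort's predicted risks at empirical quantiles into the band layout
<10 / 10-20 / 20-40 / 40-60 (reference) / 60-80 / 80-90 / >90 percent and
estimates each band's odds ratio against the reference band by indicator
logistic regression.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._logistic import fit_logit, wald_summary
from .data import Cohort
from .errors import ConfigurationError, DegenerateInputError
from .model import ModelSpec, build_design, fit_multivariable, predict_risk

#: Table-style band layout: two 10% tails, two 20% flanks, the 40-60% reference.
DEFAULT_BAND_EDGES = (0.10, 0.20, 0.40, 0.60, 0.80, 0.90)
DEFAULT_BAND_LABELS = ("<10%", "10-20%", "20-40%", "40-60%", "60-80%", "80-90%", ">90%")
REFERENCE_BAND = "40-60%"


def auc(scores, outcomes) -> float:
    """Mann-Whitney AUC: P(score_case > score_control) + P(equal)/2."""
    s = np.asarray(scores, float)
    y = np.asarray(outcomes)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise DegenerateInputError("AUC needs both cases and controls")
    ranks = stats.rankdata(s)  # average ranks implement the ties-at-1/2 convention
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class CVResult:
    """AUC distribution over repeated train/test splits."""

    aucs: np.ndarray
    n_perm: int
    train_frac: float
    seed: int
    method: str = "cv"

    @property
    def median(self) -> float:
        return float(np.median(self.aucs))

    @property
    def ci(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.aucs, [2.5, 97.5])
        return float(lo), float(hi)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"median": self.median, "ci": self.ci, "n_perm": self.n_perm,
                       "train_frac": self.train_frac, "seed": self.seed,
                       "method": self.method, "aucs": self.aucs.tolist()}, fh)


def cv_auc(cohort: Cohort | pd.DataFrame, spec: ModelSpec, n_perm: int = 1000,
           train_frac: float = 0.9, seed: int = 0,
           stratified: bool = False, max_resample: int = 50) -> CVResult:
    """Cross-validated AUC: for each of ``n_perm`` replicates draw a random
    ``train_frac`` split, fit ``spec`` on the training women and score the
    AUC on the held-out women.

    Unstratified splits that land a single-class test set are redrawn (with
    a warning) up to ``max_resample`` times; ``stratified=True`` splits
    cases and controls proportionally instead.
    """
    df = cohort.phenotypes if isinstance(cohort, Cohort) else cohort
    y = df["outcome"].to_numpy()
    n = len(df)
    n_train = int(round(train_frac * n))
    if not 0 < n_train < n:
        raise ConfigurationError(f"train_frac {train_frac} leaves no test set at n={n}")
    rng = np.random.default_rng(seed)
    design = build_design(df, spec)
    Xv = design.to_numpy(float)
    cols = design.columns
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)

    aucs = np.empty(n_perm)
    for r in range(n_perm):
        if stratified:
            tr_cases = rng.choice(case_idx, int(round(train_frac * len(case_idx))),
                                  replace=False)
            tr_ctrls = rng.choice(ctrl_idx, int(round(train_frac * len(ctrl_idx))),
                                  replace=False)
            train = np.zeros(n, bool)
            train[tr_cases] = True
            train[tr_ctrls] = True
        else:
            for attempt in range(max_resample):
                train = np.zeros(n, bool)
                train[rng.choice(n, n_train, replace=False)] = True
                if len(np.unique(y[~train])) == 2 and len(np.unique(y[train])) == 2:
                    break
                warnings.warn("single-class split redrawn", stacklevel=2)
            else:
                raise DegenerateInputError(
                    "could not draw a two-class test split; use stratified=True")
        res = fit_logit(pd.DataFrame(Xv[train], columns=cols), y[train],
                        check_rank=(r == 0))
        eta = Xv[~train] @ res.params.to_numpy()
        aucs[r] = auc(eta, y[~train])
    return CVResult(aucs, n_perm, train_frac, seed,
                    method="stratified-cv" if stratified else "cv")


def compare_auc(cv_a: CVResult, cv_b: CVResult, method: str = "wilcoxon") -> dict:
    """Paired two-sided test on per-replicate AUC differences.

    Requires the two CV runs to share seed, split fraction and replicate
    count so replicates are paired by construction. Replicate dependence
    (shared women across splits) makes the p-value approximate.
    """
    if (cv_a.seed, cv_a.n_perm, cv_a.train_frac) != (cv_b.seed, cv_b.n_perm, cv_b.train_frac):
        raise ConfigurationError("CV results are not paired (seed/n_perm/train_frac differ)")
    diffs = cv_a.aucs - cv_b.aucs
    if np.allclose(diffs, 0):
        return {"p": 1.0, "median_diff": 0.0, "method": method}
    if method == "wilcoxon":
        stat, p = stats.wilcoxon(diffs, alternative="two-sided")
    elif method == "ttest":
        stat, p = stats.ttest_1samp(diffs, 0.0)
    else:
        raise ConfigurationError(f"unknown method {method!r}")
    return {"p": float(p), "statistic": float(stat),
            "median_diff": float(np.median(diffs)), "method": method}


def stratify_bands(scores, band_edges=DEFAULT_BAND_EDGES,
                   labels=DEFAULT_BAND_LABELS) -> pd.Series:
    """Assign each woman to a risk band by empirical quantiles of the full
    cohort's scores; ties at a cut point go to the lower band."""
    s = pd.Series(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ConfigurationError("scores must be finite")
    cuts = np.quantile(s, band_edges)
    if len(np.unique(cuts)) < len(cuts) or s.nunique() <= len(cuts):
        raise DegenerateInputError(
            "too few distinct scores to form the requested bands")
    idx = np.searchsorted(cuts, s.to_numpy(), side="left")
    return pd.Series(pd.Categorical.from_codes(idx, categories=list(labels)),
                     index=s.index, name="band")


@dataclass
class StratificationReport:
    """Per-band odds ratios versus the reference band plus the case/control
    distribution over bands."""

    table: pd.DataFrame
    reference: str

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def band_odds_ratios(bands: pd.Series, outcomes,
                     reference: str = REFERENCE_BAND) -> StratificationReport:
    """OR of each band against the reference band by indicator logistic
    regression (each contrast restricted to that band plus the reference).

    Also reports each band's share of all controls and of all cases. Bands
    whose contrast is degenerate (empty, or a zero cell) are reported with
    an undefined OR rather than dropped.
    """
    y = pd.Series(np.asarray(outcomes), index=bands.index)
    if reference not in list(bands.cat.categories):
        raise ConfigurationError(f"reference band {reference!r} not among bands")
    ref_mask = bands == reference
    if y[ref_mask].nunique() < 2:
        raise DegenerateInputError("reference band must contain both cases and controls")
    n_cases = float((y == 1).sum())
    n_controls = float((y == 0).sum())
    rows = []
    for band in bands.cat.categories:
        in_band = bands == band
        b_cases = int((y[in_band] == 1).sum())
        b_controls = int((y[in_band] == 0).sum())
        row = {"band": band,
               "n": int(in_band.sum()),
               "pct_controls": 100.0 * b_controls / n_controls,
               "pct_cases": 100.0 * b_cases / n_cases}
        if band == reference:
            row.update({"or": 1.0, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan})
        else:
            sel = (in_band | ref_mask).to_numpy()
            X = pd.DataFrame({"const": 1.0, "band": in_band.astype(float)[sel]})
            try:
                res = fit_logit(X, y[sel])
                orv, lo, hi, p = wald_summary(res, "band")
                row.update({"or": orv, "ci_low": lo, "ci_high": hi, "p": p})
            except Exception as exc:
                row.update({"or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                            "p": np.nan, "note": f"undefined: {exc}"})
        rows.append(row)
    return StratificationReport(pd.DataFrame(rows), reference)


def stratify_cohort(cohort: Cohort | pd.DataFrame, fit,
                    band_edges=DEFAULT_BAND_EDGES,
                    labels=DEFAULT_BAND_LABELS,
                    reference: str = REFERENCE_BAND) -> StratificationReport:
    """Predict risk with ``fit``, band the cohort and report band ORs."""
    df = cohort.phenotypes if isinstance(cohort, Cohort) else cohort
    pred = predict_risk(fit, df)
    bands = stratify_bands(pred["probability"], band_edges, labels)
    return band_odds_ratios(bands, df["outcome"], reference)
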