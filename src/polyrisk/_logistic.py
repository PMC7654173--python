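"""Internal wrapper around statsmodels maximum-likelihood logistic fits.

Centralises the failure handling every caller needs: rank checks before the
fit, separation and non-convergence surfaced as package errors.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (ConvergenceWarning,
                                             PerfectSeparationError,
                                             PerfectSeparationWarning)

from .errors import ConvergenceError, RankDeficiencyError, SeparationError


def fit_logit(X: pd.DataFrame, y, check_rank: bool = True, maxiter: int = 100):
    """ML logistic fit of binary ``y`` on design ``X`` (must include the
    intercept column). Returns the statsmodels results object."""
    Xv = np.asarray(X, float)
    yv = np.asarray(y, float)
    if check_rank and np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise RankDeficiencyError(
            f"design matrix is rank deficient ({Xv.shape[1]} columns, "
            f"rank {np.linalg.matrix_rank(Xv)})")
    model = sm.Logit(yv, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            # non-convergence is re-raised below as ConvergenceError
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = model.fit(disp=0, maxiter=maxiter)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError() from exc
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError("logistic fit did not converge")
    # huge coefficients with huge SEs are the quasi-separated regime that
    # slips past statsmodels' own check
    if np.any(np.abs(res.params) > 30):
        raise SeparationError("coefficients diverged; data are (quasi-)separated")
    return res


def wald_summary(res, name):
    """(OR, CI low, CI high, p) for one named coefficient."""
    beta = float(res.params[name])
    se = float(res.bse[name])
    lo, hi = beta - 1.96 * se, beta + 1.96 * se
    return float(np.exp(beta)), float(np.exp(lo)), float(np.exp(hi)), float(res.pvalues[name])
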