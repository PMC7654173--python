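"""Panel filtering, genotype QC, PRS computation and genotype PCs.

The polygenic risk score of sample *i* is the weighted allele count

    PRS_i = sum_k beta_k x_ik,      beta_k = log(OR_k),

over the retained panel, with x_ik the effect-allele count (0, 1, 2). A
``weights="or"`` switch substitutes the raw per-allele OR for beta_k, for
comparison with scores published on that literal scale. Scores are reported
raw, normalized (divided by the control median) and standardized
(control mean 0, control SD 1); association models use the standardized
scale, whose coefficient is an OR per control SD.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import (STATUS_DUPLICATE, STATUS_FAILURE, GenotypeMatrix, PRSResult,
                   SNPPanel)
from .errors import ConfigurationError, MissingSNPError, PanelError, QCError

log = logging.getLogger(__name__)

#: per-allele ORs strictly inside this open interval are treated as null effects
NEAR_NULL_WINDOW = (0.95, 1.05)


def filter_snp_panel(panel: SNPPanel,
                     window: tuple[float, float] = NEAR_NULL_WINDOW
                     ) -> tuple[SNPPanel, pd.DataFrame]:
    """Drop near-null and failed SNPs from the weight panel.

    Removes SNPs whose OR lies strictly inside ``window`` (regardless of
    their status flag) and SNPs flagged ``genotyping_failure`` or
    ``duplicate_error``. Returns the retained panel and a removal log with
    one row per dropped SNP and its reason.
    """
    lo, hi = window
    df = panel.table
    near_null = (df["or_value"] > lo) & (df["or_value"] < hi)
    failed = df["status"].isin((STATUS_FAILURE, STATUS_DUPLICATE))
    drop = near_null | failed
    reasons = np.where(near_null, "near_null", df["status"])
    removal_log = pd.DataFrame({
        "rsid": df.loc[drop, "rsid"],
        "or_value": df.loc[drop, "or_value"],
        "reason": reasons[drop.to_numpy()],
    }).reset_index(drop=True)
    retained = df.loc[~drop].copy()
    if retained.empty:
        raise PanelError("panel filtering removed every SNP; the PRS is undefined")
    for _, row in removal_log.iterrows():
        log.info("panel filter: dropped %s (%s, OR=%.4f)",
                 row.rsid, row.reason, row.or_value)
    return SNPPanel(retained), removal_log


def qc_samples(gt: GenotypeMatrix, threshold: float = 0.95
               ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop samples whose call rate over the panel is below ``threshold``."""
    if not 0 < threshold <= 1:
        raise ConfigurationError(f"call-rate threshold must be in (0, 1], got {threshold}")
    rates = gt.call_rate_per_sample()
    drop = rates < threshold
    dropped = pd.DataFrame({"sample_id": rates.index[drop],
                            "call_rate": rates[drop].to_numpy()}).reset_index(drop=True)
    if drop.all():
        raise QCError(f"sample QC at threshold {threshold} removed every sample")
    for row in dropped.itertuples(index=False):
        log.info("sample QC: dropped %s (call rate %.4f)", row.sample_id, row.call_rate)
    return GenotypeMatrix(gt.dosages.loc[~drop].copy()), dropped


def qc_snps(gt: GenotypeMatrix, threshold: float = 0.95,
            panel: SNPPanel | None = None) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop SNPs with genotyping rate below ``threshold`` and SNPs flagged
    ``duplicate_error`` in the panel (when a panel is given)."""
    if not 0 < threshold <= 1:
        raise ConfigurationError(f"call-rate threshold must be in (0, 1], got {threshold}")
    rates = gt.call_rate_per_snp()
    low = rates < threshold
    reasons = pd.Series(np.where(low, "low_call_rate", ""), index=rates.index)
    if panel is not None:
        flagged = panel.table.loc[panel.table["status"] == STATUS_DUPLICATE, "rsid"]
        dup = rates.index.isin(flagged)
        reasons[dup & ~low] = "duplicate_error"
        low = low | dup
    dropped = pd.DataFrame({"rsid": rates.index[low],
                            "call_rate": rates[low].to_numpy(),
                            "reason": reasons[low].to_numpy()}).reset_index(drop=True)
    if low.all():
        raise QCError(f"SNP QC at threshold {threshold} removed every SNP")
    for row in dropped.itertuples(index=False):
        log.info("SNP QC: dropped %s (%s, rate %.4f)", row.rsid, row.reason, row.call_rate)
    return GenotypeMatrix(gt.dosages.loc[:, ~low].copy()), dropped


def compute_prs(gt: GenotypeMatrix, panel: SNPPanel,
                missing_policy: str = "expected_dosage",
                weights: str = "log_or") -> pd.Series:
    """Per-sample raw score sum_k beta_k x_ik over the panel SNPs.

    missing_policy
        ``"expected_dosage"`` substitutes 2*eaf_k for a missing call
        (default), ``"zero"`` substitutes 0, ``"drop"`` omits the SNP from
        that sample's sum.
    weights
        ``"log_or"`` (beta = log OR, default) or ``"or"`` (beta = OR, the
        literal published-table reading).
    """
    absent = [r for r in panel.rsids if r not in set(gt.rsids)]
    if absent:
        raise MissingSNPError(absent)
    if missing_policy not in ("expected_dosage", "zero", "drop"):
        raise ConfigurationError(f"unknown missing_policy {missing_policy!r}")
    if weights not in ("log_or", "or"):
        raise ConfigurationError(f"unknown weights scale {weights!r}")

    x = gt.dosages[list(panel.rsids)].to_numpy(float)
    beta = panel.weights if weights == "log_or" else panel.or_values
    if not np.isfinite(beta).all():
        raise PanelError("non-finite panel weights")
    miss = np.isnan(x)
    if miss.any():
        if missing_policy == "expected_dosage":
            x = np.where(miss, 2.0 * panel.eaf, x)
        else:  # "zero" and "drop" both contribute nothing to the sum
            x = np.where(miss, 0.0, x)
    raw = x @ beta
    return pd.Series(raw, index=gt.sample_ids, name="prs_raw")


def normalize_prs(raw: pd.Series, control_ids) -> PRSResult:
    """Attach the control-median-normalized and control-standardized scales.

    Requires at least two controls with finite raw scores; errors out when
    the control median is zero (the ratio scale is then undefined and the
    standardized scale should be used alone).
    """
    controls = raw.loc[list(control_ids)]
    controls = controls[np.isfinite(controls)]
    if len(controls) < 2:
        raise ConfigurationError("normalization needs >= 2 controls with finite scores")
    med = float(controls.median())
    mean = float(controls.mean())
    sd = float(controls.std(ddof=1))
    if med == 0.0:
        raise ConfigurationError(
            "control median PRS is 0; the median-normalized scale is undefined "
            "- use the standardized scale")
    if sd == 0.0:
        raise ConfigurationError("control PRS SD is 0; standardization undefined")
    return PRSResult(
        raw=raw,
        normalized=raw / med,
        standardized=(raw - mean) / sd,
        qc_report={"control_median": med, "control_mean": mean, "control_sd": sd,
                   "n_controls": int(len(controls))},
    )


def genotype_pcs(gt: GenotypeMatrix, k: int = 5, scale: str = "unit") -> pd.DataFrame:
    """First ``k`` principal components of the dosage matrix.

    Missing calls are mean-imputed per SNP; columns are centred and scaled
    to unit variance (``scale="hwe"`` divides by sqrt(2p(1-p)) instead,
    with p the observed allele frequency); monomorphic SNPs are dropped.
    Coordinates are ordered by decreasing explained variance with each
    component's sign fixed so its largest-magnitude SNP loading is positive.
    """
    x = gt.dosages.to_numpy(float).copy()
    n, m = x.shape
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    col_mean = np.nanmean(x, axis=0)
    miss = np.isnan(x)
    x[miss] = np.take(col_mean, np.nonzero(miss)[1])
    x -= col_mean
    if scale == "unit":
        sd = x.std(axis=0, ddof=1)
    elif scale == "hwe":
        p = col_mean / 2.0
        sd = np.sqrt(2.0 * p * (1.0 - p))
    else:
        raise ConfigurationError(f"unknown PC scaling {scale!r}")
    keep = sd > 0
    x = x[:, keep] / sd[keep]
    rank = min(n - 1, int(keep.sum()))
    if k > rank:
        raise ConfigurationError(
            f"requested {k} PCs but the centred matrix has rank <= {rank}")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest-|loading| SNP positive per component
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    coords = u[:, :k] * s[:k]
    return pd.DataFrame(coords, index=gt.sample_ids,
                        columns=[f"PC{i + 1}" for i in range(k)])
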