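"""End-to-end pipeline: QC -> PRS -> encoding -> screens -> model -> evaluation.

Mirrors the analysis plan of a combined genotype + phenotype case-control
study: filter the weight panel, QC samples and SNPs, compute and normalize
the PRS, encode phenotypes, screen factors univariably (selection at
two-sided p < 0.05, with family history and menarche forced in), test the
candidate age interactions by LRT, fit the multivariable model with and
without the selected interactions, check calibration (Hosmer-Lemeshow),
estimate cross-validated AUC for both variants, and stratify the cohort
into risk bands against the 40-60% reference. Every artifact is written to
the output directory together with a manifest (config hash, seed, package
versions, hashes of all numeric outputs) for reproducibility audits.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (SIGNIFICANCE_THRESHOLD, interaction_lrt, prs_association,
                          spearman_independence, univariable_fit)
from .config import SimulationConfig
from .data import FACTORS, Cohort
from .errors import ConfigurationError, PipelineStageError
from .evaluation import (CVResult, StratificationReport, compare_auc, cv_auc,
                         stratify_cohort)
from .io import read_encoding_tsv, read_inputs
from .model import (DEFAULT_FORCED, DEFAULT_INTERACTIONS, ModelSpec, fit_model,
                    hosmer_lemeshow, predict_risk)
from .phenotypes import FactorEncoding, encode_cohort, validate_phenotypes
from .prs import compute_prs, filter_snp_panel, genotype_pcs, normalize_prs, qc_samples, qc_snps
from .simulate import simulate_cohort

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Exactly one of ``simulation`` (generate a synthetic cohort) or
    ``inputs`` (paths: panel, genotypes, phenotypes, encodings) must be set.
    """

    simulation: SimulationConfig | None = None
    inputs: dict | None = None
    sample_call_rate: float = 0.95
    snp_call_rate: float = 0.95
    selection_p: float = SIGNIFICANCE_THRESHOLD
    forced_factors: tuple[str, ...] = DEFAULT_FORCED
    interaction_candidates: tuple[tuple[str, str], ...] = DEFAULT_INTERACTIONS
    include_interactions: bool = True
    n_pcs: int = 5
    n_perm: int = 1000
    train_frac: float = 0.9
    seed: int = 0
    output_dir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.simulation is None) == (self.inputs is None):
            raise ConfigurationError(
                "exactly one of 'simulation' and 'inputs' must be configured")
        for name, th in (("sample_call_rate", self.sample_call_rate),
                         ("snp_call_rate", self.snp_call_rate)):
            if not 0 < th <= 1:
                raise ConfigurationError(f"{name} must be in (0, 1], got {th}")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        sim = raw.pop("simulation", None)
        if sim is not None:
            if "phenotype_specs" in sim:
                from .config import PhenotypeSpec
                sim["phenotype_specs"] = tuple(
                    PhenotypeSpec(**{k: tuple(v) if isinstance(v, list) else v
                                     for k, v in s.items()})
                    for s in sim["phenotype_specs"])
            for key in ("maf_range", "age_bin_probs", "per_allele_log_or"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            if "interaction_terms" in sim:
                sim["interaction_terms"] = tuple(tuple(t) for t in sim["interaction_terms"])
            sim = SimulationConfig(**sim)
        for key in ("forced_factors",):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "interaction_candidates" in raw:
            raw["interaction_candidates"] = tuple(tuple(t) for t in raw["interaction_candidates"])
        return cls(simulation=sim, **raw)

    def to_jsonable(self) -> dict:
        out = dataclasses.asdict(self)
        return out


@dataclass
class PipelineResult:
    """Everything a run produced, plus the manifest."""

    cohort: Cohort
    panel: object
    prs: object
    pcs: pd.DataFrame
    univariable: pd.DataFrame
    prs_fit: object
    interactions: list
    selected_factors: tuple
    selected_interactions: tuple
    fit_interaction: object
    fit_plain: object
    hosmer_lemeshow: dict
    cv_interaction: CVResult
    cv_plain: CVResult
    auc_comparison: dict
    stratification: StratificationReport
    spearman: tuple
    manifest: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return wrapped
    return deco


def _hash_array(arr) -> str:
    a = np.ascontiguousarray(np.asarray(arr, float))
    return hashlib.sha256(np.round(a, 10).tobytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; see the module docstring for the stages."""
    logging.basicConfig(level=config.log_level)
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=8)

    # --- inputs -----------------------------------------------------------
    if config.simulation is not None:
        panel, cohort = _stage("simulate")(simulate_cohort)(config.simulation)
        encodings = {s.name: FactorEncoding.from_spec(s)
                     for s in config.simulation.phenotype_specs}
    else:
        paths = config.inputs
        panel, _gt, cohort = _stage("read_inputs")(read_inputs)(
            paths["panel"], paths["genotypes"], paths["phenotypes"])
        encodings = _stage("read_inputs")(read_encoding_tsv)(paths["encodings"])

    # --- QC / PRS ---------------------------------------------------------
    panel_f, removal_log = _stage("filter_panel")(filter_snp_panel)(panel)
    gt = cohort.genotypes.subset_snps(
        [r for r in cohort.genotypes.rsids if r in set(panel_f.rsids)])
    gt, dropped_samples = _stage("qc_samples")(qc_samples)(gt, config.sample_call_rate)
    gt, dropped_snps = _stage("qc_snps")(qc_snps)(gt, config.snp_call_rate, panel_f)
    panel_f = panel_f.subset(gt.rsids)
    cohort = cohort.subset(gt.sample_ids)
    cohort = Cohort(cohort.phenotypes, gt)

    raw = _stage("prs")(compute_prs)(gt, panel_f)
    prs = _stage("prs")(normalize_prs)(raw, cohort.control_ids)
    pcs = _stage("pcs")(genotype_pcs)(gt, k=config.n_pcs)

    # --- phenotype encoding ----------------------------------------------
    phen, validation = _stage("phenotypes")(validate_phenotypes)(
        cohort.phenotypes, exclude=True)
    cohort = cohort.subset(phen.index)
    cohort = _stage("phenotypes")(encode_cohort)(cohort, encodings)
    df = cohort.phenotypes
    df["prs_std"] = prs.standardized.loc[df.index]
    df["prs_normalized"] = prs.normalized.loc[df.index]

    # --- univariable screen ----------------------------------------------
    uni_rows, selected = [], []
    for factor in FACTORS:
        fit = _stage("univariable")(univariable_fit)(df, factor)
        uni_rows.append(fit.row())
        keep = fit.p_value < config.selection_p or factor in config.forced_factors
        if keep:
            selected.append(factor)
        log.info("univariable %s: OR=%.3f p=%.3g -> %s", factor, fit.or_per_unit,
                 fit.p_value, "selected" if keep else "dropped")
    univariable = pd.DataFrame(uni_rows)

    prs_fit = _stage("prs_association")(prs_association)(df, prs, pcs)
    selected.append("prs")
    log.info("PRS per-SD OR=%.3f (%.3f-%.3f) p=%.3g", prs_fit.or_per_unit,
             prs_fit.ci_low, prs_fit.ci_high, prs_fit.p_value)

    # --- interactions -----------------------------------------------------
    interactions = []
    selected_inter = []
    if config.include_interactions:
        for a, b in config.interaction_candidates:
            lrt = _stage("interaction_lrt")(interaction_lrt)(df, a, b)
            interactions.append(lrt)
            if lrt["p"] < config.selection_p and \
                    all(f in selected or f == "age" for f in (a, b)):
                selected_inter.append((a, b))
            log.info("interaction %s x %s: LRT=%.2f p=%.3g", a, b, lrt["lrt"], lrt["p"])

    # --- multivariable models --------------------------------------------
    spec_plain = ModelSpec(tuple(selected), ())
    spec_inter = ModelSpec(tuple(selected), tuple(selected_inter))
    fit_plain = _stage("fit_multivariable")(fit_model)(df, spec_plain)
    fit_inter = _stage("fit_multivariable")(fit_model)(df, spec_inter)
    pred = predict_risk(fit_inter, df)
    hl = _stage("hosmer_lemeshow")(hosmer_lemeshow)(pred["probability"], df["outcome"])

    # --- evaluation -------------------------------------------------------
    cv_inter = _stage("cv_auc")(cv_auc)(df, spec_inter, config.n_perm,
                                        config.train_frac, seed=int(seeds[0]))
    cv_plain = _stage("cv_auc")(cv_auc)(df, spec_plain, config.n_perm,
                                        config.train_frac, seed=int(seeds[0]))
    comparison = compare_auc(cv_inter, cv_plain) if config.n_perm > 1 else {}
    strat = _stage("stratify")(stratify_cohort)(df, fit_inter)
    spearman = _stage("spearman")(spearman_independence)(
        df, ["prs_std"] + [f"{f}_enc" for f in FACTORS])

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "n_samples": int(len(df)),
        "n_cases": cohort.n_cases,
        "n_controls": cohort.n_controls,
        "n_snps_input": int(len(panel)),
        "n_snps_retained": int(len(panel_f)),
        "n_samples_dropped_qc": int(len(dropped_samples)),
        "n_snps_dropped_qc": int(len(dropped_snps)),
        "phenotype_exclusions": validation["n_flagged"],
        "selected_factors": selected,
        "selected_interactions": [list(t) for t in selected_inter],
        "hashes": {
            "prs_raw": _hash_array(prs.raw),
            "pcs": _hash_array(pcs),
            "predictions": _hash_array(pred["probability"]),
            "cv_aucs_interaction": _hash_array(cv_inter.aucs),
            "cv_aucs_plain": _hash_array(cv_plain.aucs),
            "band_or": _hash_array(strat.table["or"].fillna(-1.0)),
        },
        "results": {
            "prs_or_per_sd": prs_fit.or_per_unit,
            "cv_auc_interaction": cv_inter.median,
            "cv_auc_plain": cv_plain.median,
            "auc_comparison_p": comparison.get("p"),
            "hosmer_lemeshow_p": hl["p"],
        },
    }

    result = PipelineResult(
        cohort=cohort, panel=panel_f, prs=prs, pcs=pcs, univariable=univariable,
        prs_fit=prs_fit, interactions=interactions,
        selected_factors=tuple(selected), selected_interactions=tuple(selected_inter),
        fit_interaction=fit_inter, fit_plain=fit_plain, hosmer_lemeshow=hl,
        cv_interaction=cv_inter, cv_plain=cv_plain, auc_comparison=comparison,
        stratification=strat, spearman=spearman, manifest=manifest)

    if config.output_dir is not None:
        _write_artifacts(result, prs, pcs, pred, removal_log, config)
    return result


def _write_artifacts(result, prs, pcs, pred, removal_log, config):
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    prs.frame().to_csv(out / "prs.tsv", sep="\t")
    pcs.to_csv(out / "pcs.tsv", sep="\t")
    pred.to_csv(out / "predictions.tsv", sep="\t")
    removal_log.to_csv(out / "panel_removals.tsv", sep="\t", index=False)
    result.univariable.to_csv(out / "univariable.tsv", sep="\t", index=False)
    result.stratification.to_tsv(out / "stratification.tsv")
    result.cv_interaction.to_json(out / "cv_auc_interaction.json")
    result.cv_plain.to_json(out / "cv_auc_plain.json")
    result.fit_interaction.to_json(out / "model_interaction.json")
    result.fit_plain.to_json(out / "model_plain.json")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1, default=str)
    log.info("artifacts written to %s", out)
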