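"""Synthetic case-control cohort generator.

Cohorts are generated in two steps that mirror a retrospective case-control
design. First a prospective population is drawn: independent biallelic SNP
genotypes under Hardy-Weinberg equilibrium, categorical risk factors drawn
from their control-category frequencies, ages by 5-year bin, and a
case/control outcome from a prospective logistic disease model

    logit P(case) = baseline + sum_k beta_k x_k + factor effects
                    + interaction terms + centre shift.

Second, a fixed number of cases and controls is subsampled uniformly
(ascertainment), which preserves odds ratios but not absolute risk. By
default every effect term is mean-centred over its generative distribution
so that ``baseline_log_odds`` pins the approximate population prevalence;
centring only reparameterises the intercept and changes no odds ratio.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit  # noqa: F401  (logit re-exported for callers)

from .config import AGE_BIN_EDGES, SimulationConfig
from .data import (STATUS_DUPLICATE, STATUS_FAILURE, STATUS_NEAR_NULL,
                   STATUS_OK, Cohort, GenotypeMatrix, SNPPanel)
from .errors import AscertainmentError, ConfigurationError

_NEAR_NULL_WINDOW = (0.95, 1.05)
_ALLELE_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT" if a != b]


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent, reproducible generator per (seed, stage) pair."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


@dataclass
class PopulationDraw:
    """A prospective population: genotypes, phenotypes (with outcome and
    per-person linear predictor) and the panel truth it was generated from."""

    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    linear_predictor: pd.Series

    @property
    def outcome(self) -> pd.Series:
        return self.phenotypes["outcome"]


def generate_snp_panel(config: SimulationConfig) -> SNPPanel:
    """Draw a SNP weight panel.

    Unflagged SNPs receive per-allele ORs strictly outside the near-null
    window (0.95, 1.05); ``n_near_null`` SNPs get ORs strictly inside it and
    ``n_failed`` / ``n_duplicate_error`` SNPs are flagged for the QC filters.
    Identical config (including seed) gives an identical panel.
    """
    rng = _rng(config.seed, 0)
    n = config.n_snps
    eaf = rng.uniform(*config.maf_range, size=n)

    if config.per_allele_log_or is not None:
        log_or = np.asarray(config.per_allele_log_or, float)
    else:
        log_or = rng.normal(0.0, config.log_or_sd, size=n)
        # resample any draw that lands in the near-null window; flagged
        # near-null SNPs are overwritten below
        lo, hi = np.log(_NEAR_NULL_WINDOW)
        inside = (log_or > lo) & (log_or < hi)
        while inside.any():
            log_or[inside] = rng.normal(0.0, config.log_or_sd, size=int(inside.sum()))
            inside = (log_or > lo) & (log_or < hi)

    status = np.array([STATUS_OK] * n, dtype=object)
    flagged = rng.permutation(n)[: config.n_near_null + config.n_failed
                                 + config.n_duplicate_error]
    near_idx = flagged[: config.n_near_null]
    fail_idx = flagged[config.n_near_null: config.n_near_null + config.n_failed]
    dup_idx = flagged[config.n_near_null + config.n_failed:]
    status[near_idx] = STATUS_NEAR_NULL
    status[fail_idx] = STATUS_FAILURE
    status[dup_idx] = STATUS_DUPLICATE
    if len(near_idx):
        lo, hi = np.log(_NEAR_NULL_WINDOW)
        log_or[near_idx] = rng.uniform(lo + 1e-6, hi - 1e-6, size=len(near_idx))

    alleles = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), size=n)]
    table = pd.DataFrame({
        "rsid": [f"rs{1_000_000 + i}" for i in range(n)],
        "effect_allele": [a for a, _ in alleles],
        "other_allele": [b for _, b in alleles],
        "or_value": np.exp(log_or),
        "eaf": eaf,
        "status": status,
    })
    return SNPPanel(table)


def calibrate_panel_per_sd_effect(panel: SNPPanel, per_sd_log_odds: float) -> SNPPanel:
    """Rescale the panel's per-allele log-ORs so the generative per-SD effect
    of the PRS equals ``per_sd_log_odds``.

    Under HWE with independent SNPs, Var(sum_k beta_k x_k) =
    sum_k beta_k^2 2 p_k (1 - p_k); scaling every beta by
    ``per_sd_log_odds / SD`` makes a one-SD increase of the true score worth
    exactly ``per_sd_log_odds`` on the log-odds scale.
    """
    beta = panel.weights
    var = float(np.sum(beta ** 2 * 2.0 * panel.eaf * (1.0 - panel.eaf)))
    if var <= 0:
        raise ConfigurationError("panel has zero generative PRS variance; cannot calibrate")
    scale = per_sd_log_odds / np.sqrt(var)
    table = panel.table.copy()
    table["or_value"] = np.exp(beta * scale)
    return SNPPanel(table)


def _draw_ages(rng, config, n):
    bins = rng.choice(len(config.age_bin_probs), size=n, p=config.age_bin_probs)
    lo = np.asarray(AGE_BIN_EDGES[:-1], float)[bins]
    hi = np.asarray(AGE_BIN_EDGES[1:], float)[bins]
    return bins, lo + rng.uniform(0.0, 1.0, size=n) * (hi - lo)


def simulate_population(panel: SNPPanel, config: SimulationConfig, n: int) -> PopulationDraw:
    """Draw ``n`` women prospectively from the disease model.

    Genotypes are Binomial(2, eaf) per SNP (HWE, no linkage); phenotype
    categories come from their control-category frequencies; the outcome is
    Bernoulli(expit(linear predictor)).
    """
    if n < 1:
        raise ConfigurationError("population size must be >= 1")
    rng = _rng(config.seed, 1)
    beta = panel.weights
    eaf = panel.eaf

    genotypes = rng.binomial(2, eaf, size=(n, len(panel))).astype(float)
    lp = genotypes @ beta
    if config.center_effects:
        lp -= float(beta @ (2.0 * eaf))

    factor_values = {}
    pheno_cols = {}
    for spec in config.phenotype_specs:
        cat_idx = rng.choice(len(spec.categories), size=n, p=spec.control_freqs)
        vals = np.asarray(spec.log_ors, float)[cat_idx]
        factor_values[spec.name] = vals
        pheno_cols[f"{spec.name}_cat"] = np.asarray(spec.categories, object)[cat_idx]
        lp += vals
        if config.center_effects:
            lp -= float(np.dot(spec.control_freqs, spec.log_ors))

    age_bins, ages = _draw_ages(rng, config, n)
    factor_values["age"] = age_bins.astype(float)
    mean_value = {name: float(np.dot(s.control_freqs, s.log_ors))
                  for name, s in ((s.name, s) for s in config.phenotype_specs)}
    mean_value["age"] = float(np.dot(config.age_bin_probs,
                                     np.arange(len(config.age_bin_probs))))

    for fa, fb, coef in config.interaction_terms:
        term = coef * factor_values[fa] * factor_values[fb]
        lp += term
        if config.center_effects:
            # factors are drawn independently, so E[va*vb] = E[va]E[vb]
            lp -= coef * mean_value[fa] * mean_value[fb]

    centre_idx = rng.integers(0, config.n_centres, size=n)
    shift = config.centre_log_odds_shift * (centre_idx > 0)
    lp += shift
    if config.center_effects and config.n_centres > 1:
        lp -= config.centre_log_odds_shift * (config.n_centres - 1) / config.n_centres

    lp += config.baseline_log_odds
    outcome = rng.binomial(1, expit(lp))

    ids = pd.Index([f"S{i:06d}" for i in range(n)], name="sample_id")
    phen = pd.DataFrame({
        "outcome": outcome,
        "age": ages,
        "centre": np.asarray([f"centre_{i + 1}" for i in centre_idx], object),
        **pheno_cols,
    }, index=ids)
    gt = GenotypeMatrix(pd.DataFrame(genotypes, index=ids, columns=panel.rsids))
    return PopulationDraw(gt, phen, pd.Series(lp, index=ids, name="linear_predictor"))


def ascertain_case_control(pop: PopulationDraw, n_cases: int, n_controls: int,
                           seed: int) -> Cohort:
    """Subsample exactly ``n_cases`` cases and ``n_controls`` controls,
    uniformly without replacement, carrying all per-person fields through."""
    rng = np.random.default_rng(seed)
    is_case = pop.outcome.to_numpy() == 1
    case_ids = pop.phenotypes.index[is_case]
    control_ids = pop.phenotypes.index[~is_case]
    if len(case_ids) < n_cases or len(control_ids) < n_controls:
        raise AscertainmentError(
            f"population holds {len(case_ids)} cases / {len(control_ids)} controls; "
            f"requested {n_cases} / {n_controls} "
            f"(short by {max(0, n_cases - len(case_ids))} cases, "
            f"{max(0, n_controls - len(control_ids))} controls)")
    picked_cases = rng.choice(case_ids, size=n_cases, replace=False)
    picked_controls = rng.choice(control_ids, size=n_controls, replace=False)
    ids = pop.phenotypes.index[pop.phenotypes.index.isin(
        np.concatenate([picked_cases, picked_controls]))]
    phen = pop.phenotypes.loc[ids].copy()
    gt = pop.genotypes.subset_samples(ids)
    return Cohort(phen, gt)


def simulate_cohort(config: SimulationConfig, oversample: float = 3.0,
                    max_draws: int = 6) -> tuple[SNPPanel, Cohort]:
    """Convenience wrapper: panel + population + ascertainment in one call.

    The population is grown geometrically until it holds enough cases and
    controls for the requested ascertainment.
    """
    panel = generate_snp_panel(config)
    n = int(oversample * (config.n_cases + config.n_controls))
    for attempt in range(max_draws):
        pop = simulate_population(panel, config.with_(seed=config.seed + attempt * 7919), n)
        try:
            cohort = ascertain_case_control(pop, config.n_cases, config.n_controls,
                                            seed=config.seed)
            return panel, cohort
        except AscertainmentError:
            n *= 2
    raise AscertainmentError(
        f"could not accumulate {config.n_cases} cases / {config.n_controls} controls "
        f"after {max_draws} population draws; adjust baseline_log_odds")


def write_fixture(cohort: Cohort, panel: SNPPanel, directory) -> dict:
    """Write a complete on-disk fixture: panel TSV, dosage TSV, phenotype CSV
    and a VCF, all round-trippable through :mod:`polyrisk.io`."""
    from . import io as pio
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "panel": directory / "panel.tsv",
        "dosages": directory / "dosages.tsv",
        "phenotypes": directory / "phenotypes.csv",
        "vcf": directory / "genotypes.vcf",
    }
    pio.write_panel_tsv(panel, paths["panel"])
    pio.write_dosage_tsv(cohort.genotypes, paths["dosages"])
    pio.write_phenotype_csv(cohort.phenotypes, paths["phenotypes"])
    pio.write_vcf(cohort.genotypes, panel, paths["vcf"])
    return paths
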