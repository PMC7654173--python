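"""Simulation and pipeline configuration.

The synthetic cohort generator is parameterised by :class:`SimulationConfig`.
Its defaults encode the study conditions the package targets: 642 controls
and 455 cases aged 30-70 (eight 5-year bins), 92 biallelic SNPs under
Hardy-Weinberg equilibrium, five categorical risk factors whose control
category frequencies mirror a population-based Spanish screening cohort,
two recruitment centres, and an assumed disease prevalence of 12%.

Per-category effect sizes are configuration data, never literature constants:
the defaults below are synthetic example values with literature-plausible
directions (documented in docs/methods.md), supplied so that the generator is
usable out of the box.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

#: 5-year age bins spanning 30-70, with the top bin closed at 70.
AGE_BIN_EDGES = (30, 35, 40, 45, 50, 55, 60, 65, 70)
AGE_BIN_LABELS = ("30-35", "35-40", "40-45", "45-50", "50-55",
                  "55-60", "60-65", ">65")

#: Control-column age-bin percentages of the emulated cohort (renormalised;
#: the printed column sums to 99.99%).
_AGE_PCT = (4.36, 9.03, 13.08, 21.50, 24.61, 17.60, 7.32, 2.49)
DEFAULT_AGE_BIN_PROBS = tuple(p / sum(_AGE_PCT) for p in _AGE_PCT)


@dataclass(frozen=True)
class PhenotypeSpec:
    """One categorical risk factor: ordered labels, control-category
    frequencies and per-category log odds ratios (reference category 0)."""

    name: str
    categories: tuple[str, ...]
    control_freqs: tuple[float, ...]
    log_ors: tuple[float, ...]

    def __post_init__(self):
        k = len(self.categories)
        if len(self.control_freqs) != k or len(self.log_ors) != k:
            raise ConfigurationError(
                f"factor '{self.name}': categories, frequencies and log-ORs "
                f"must have equal length")
        if any(f < 0 for f in self.control_freqs):
            raise ConfigurationError(f"factor '{self.name}': negative category frequency")
        if abs(sum(self.control_freqs) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"factor '{self.name}': category frequencies sum to "
                f"{sum(self.control_freqs):.6f}, expected 1")

    @property
    def ors(self) -> tuple[float, ...]:
        return tuple(math.exp(b) for b in self.log_ors)


def _renorm(percentages):
    total = sum(percentages)
    return tuple(p / total for p in percentages)


def default_phenotype_specs() -> tuple[PhenotypeSpec, ...]:
    """The five default risk factors.

    Category labels and control frequencies follow the emulated cohort's
    control column; the log-ORs are synthetic defaults with conventional
    directions (denser breasts, later first delivery, pre-menopausal status
    at diagnosis age, earlier menarche and stronger family history all
    increase risk).
    """
    return (
        PhenotypeSpec(
            "density",
            ("0-10%", "11-25%", "26-50%", "51-75%", ">75%"),
            _renorm((15.42, 18.07, 28.82, 28.19, 9.50)),
            tuple(math.log(o) for o in (1.0, 1.25, 1.6, 2.1, 3.0)),
        ),
        PhenotypeSpec(
            "first_delivery",
            ("<20", "20-24", "25-29", "30-34", ">34", "Nulliparous"),
            _renorm((5.14, 25.70, 31.62, 16.51, 8.72, 12.31)),
            tuple(math.log(o) for o in (1.0, 1.1, 1.2, 1.35, 1.55, 1.35)),
        ),
        PhenotypeSpec(
            "menopause",
            ("<46", "46-50", ">50", "Premenopause", "Menstruating"),
            _renorm((15.11, 22.90, 17.13, 13.55, 31.30)),
            tuple(math.log(o) for o in (1.0, 1.15, 1.3, 2.0, 1.7)),
        ),
        PhenotypeSpec(
            "menarche",
            (">=15", "14", "13", "12", "<12", "Null"),
            _renorm((5.30, 17.90, 27.73, 21.81, 27.26, 0.0)),
            tuple(math.log(o) for o in (1.0, 1.05, 1.1, 1.15, 1.25, 1.0)),
        ),
        PhenotypeSpec(
            "family",
            ("none", "first_deg_50plus", "first_deg_under50", "one_second_deg",
             "two_first_deg", "two_second_deg", "three_plus"),
            _renorm((72.90, 8.10, 3.89, 14.02, 0.62, 0.16, 0.31)),
            tuple(math.log(o) for o in (1.0, 1.45, 2.0, 1.3, 2.5, 1.6, 2.9)),
        ),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Generative model for a synthetic case-control cohort.

    Parameters
    ----------
    n_snps : number of biallelic SNPs on the panel.
    maf_range : range from which effect-allele frequencies are drawn,
        within (0, 0.5].
    per_allele_log_or : optional explicit per-SNP log odds ratios; when
        ``None`` they are drawn N(0, log_or_sd) excluding the near-null OR
        window unless near-null SNPs are explicitly requested.
    log_or_sd : SD of drawn per-allele log-ORs.
    n_near_null : SNPs injected with OR strictly inside (0.95, 1.05).
    n_failed : SNPs flagged as platform genotyping failures.
    n_duplicate_error : SNPs flagged as failing control-duplicate checks.
    phenotype_specs : the categorical risk factors (see
        :func:`default_phenotype_specs`).
    age_bin_probs : probabilities over the eight 5-year age bins.
    interaction_terms : ``(factor_a, factor_b, coefficient)`` tuples; each
        contributes ``coefficient * value_a * value_b`` to the linear
        predictor, where a phenotype factor's value is its category log-OR
        and the special factor ``"age"`` contributes the age-bin index.
    baseline_log_odds : intercept of the disease model; with
        ``center_effects`` (default) it is approximately the population
        log-odds of disease. Default ``logit(0.12)``.
    centre_log_odds_shift : intercept shift applied to the second centre.
    center_effects : mean-centre every effect term over its generative
        distribution (an intercept-only reparameterisation that keeps the
        realised prevalence near ``expit(baseline_log_odds)``).
    n_cases, n_controls : ascertainment targets.
    seed : base seed for all randomness.
    """

    n_snps: int = 92
    maf_range: tuple[float, float] = (0.05, 0.5)
    per_allele_log_or: tuple[float, ...] | None = None
    log_or_sd: float = 0.08
    n_near_null: int = 0
    n_failed: int = 0
    n_duplicate_error: int = 0
    phenotype_specs: tuple[PhenotypeSpec, ...] = field(default_factory=default_phenotype_specs)
    age_bin_probs: tuple[float, ...] = DEFAULT_AGE_BIN_PROBS
    interaction_terms: tuple[tuple[str, str, float], ...] = ()
    baseline_log_odds: float = math.log(0.12 / 0.88)
    centre_log_odds_shift: float = 0.0
    n_centres: int = 2
    center_effects: bool = True
    n_cases: int = 455
    n_controls: int = 642
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(
                f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ConfigurationError("n_cases and n_controls must be positive")
        if self.n_near_null + self.n_failed + self.n_duplicate_error > self.n_snps:
            raise ConfigurationError("flagged SNP counts exceed n_snps")
        probs = np.asarray(self.age_bin_probs, float)
        if len(probs) != len(AGE_BIN_LABELS) or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"age_bin_probs must be {len(AGE_BIN_LABELS)} probabilities summing to 1")
        if self.per_allele_log_or is not None and len(self.per_allele_log_or) != self.n_snps:
            raise ConfigurationError("per_allele_log_or length must equal n_snps")
        if self.n_centres < 1:
            raise ConfigurationError("n_centres must be >= 1")
        names = {s.name for s in self.phenotype_specs}
        for a, b, _c in self.interaction_terms:
            for f in (a, b):
                if f != "age" and f not in names:
                    raise ConfigurationError(f"interaction references unknown factor '{f}'")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with fields replaced (frozen-dataclass convenience)."""
        return replace(self, **kwargs)
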