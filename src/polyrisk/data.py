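"""Core in-memory containers.

The package works on three objects: a :class:`SNPPanel` (the weight table),
a :class:`GenotypeMatrix` (samples x SNPs effect-allele counts, ``NaN`` =
missing) and a :class:`Cohort` (per-woman phenotype table plus the genotype
matrix for the same samples). All three are thin wrappers over pandas
structures so they interoperate with the rest of the scientific stack; the
wrappers only add validation and domain helpers.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PanelError, ConfigurationError

#: Panel status values understood by the QC filters.
STATUS_OK = "ok"
STATUS_NEAR_NULL = "near_null"
STATUS_FAILURE = "genotyping_failure"
STATUS_DUPLICATE = "duplicate_error"
PANEL_STATUSES = (STATUS_OK, STATUS_NEAR_NULL, STATUS_FAILURE, STATUS_DUPLICATE)

PANEL_COLUMNS = ("rsid", "effect_allele", "other_allele", "or_value", "eaf", "status")

#: Phenotypic risk factors, in the order they appear in the cohort table.
FACTORS = ("density", "first_delivery", "menopause", "menarche", "family")

#: Required columns of a phenotype table (categories still un-encoded).
PHENOTYPE_COLUMNS = (
    "sample_id", "outcome", "age", "centre",
    "density_cat", "first_delivery_cat", "menopause_cat", "menarche_cat", "family_cat",
)


@dataclass
class SNPPanel:
    """SNP weight panel: one row per SNP with its effect allele, per-allele
    odds ratio (``or_value``), effect-allele frequency (``eaf``) and a QC
    ``status`` flag.

    The per-allele log-odds weight used by the score is ``log(or_value)``;
    both scales are exposed (:attr:`weights`, :attr:`or_values`).
    """

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise PanelError(f"panel missing columns: {missing}")
        if df["rsid"].duplicated().any():
            dups = df.loc[df["rsid"].duplicated(), "rsid"].tolist()
            raise PanelError(f"duplicate rsids in panel: {dups}")
        if not (df["or_value"] > 0).all():
            raise PanelError("panel odds ratios must be strictly positive")
        bad = ~df["status"].isin(PANEL_STATUSES)
        if bad.any():
            raise PanelError(f"unknown panel status values: {sorted(df.loc[bad, 'status'].unique())}")
        if not df["eaf"].between(0, 1, inclusive="neither").all():
            raise PanelError("effect-allele frequencies must lie in (0, 1)")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def rsids(self) -> pd.Index:
        return pd.Index(self.table["rsid"])

    @property
    def or_values(self) -> np.ndarray:
        return self.table["or_value"].to_numpy(float)

    @property
    def weights(self) -> np.ndarray:
        """Per-allele log-odds, ``log(OR)``."""
        return np.log(self.or_values)

    @property
    def eaf(self) -> np.ndarray:
        return self.table["eaf"].to_numpy(float)

    def subset(self, rsids) -> "SNPPanel":
        keep = self.table["rsid"].isin(list(rsids))
        return SNPPanel(self.table.loc[keep].copy())


@dataclass
class GenotypeMatrix:
    """Samples x SNPs effect-allele counts.

    ``dosages`` is indexed by sample id with one column per rsid; values are
    0/1/2 with ``NaN`` for a missing call.
    """

    dosages: pd.DataFrame

    def __post_init__(self):
        vals = self.dosages.to_numpy(float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(vals[~ok])
            raise ConfigurationError(f"genotype dosages must be 0/1/2/missing; found {bad}")
        if self.dosages.index.duplicated().any():
            raise ConfigurationError("duplicate sample ids in genotype matrix")

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def rsids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def call_rate_per_sample(self) -> pd.Series:
        return self.dosages.notna().mean(axis=1)

    def call_rate_per_snp(self) -> pd.Series:
        return self.dosages.notna().mean(axis=0)

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.loc[list(sample_ids)].copy())

    def subset_snps(self, rsids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[list(rsids)].copy())


@dataclass
class PRSResult:
    """Per-sample polygenic score on three scales plus the QC trail.

    raw            Sum of per-allele weights times effect-allele counts.
    normalized     raw / median(raw over retained controls); the cohort-median
                   scale the score is reported on.
    standardized   (raw - control mean) / control SD; the per-SD scale used in
                   association models.
    """

    raw: pd.Series
    normalized: pd.Series | None = None
    standardized: pd.Series | None = None
    qc_report: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"raw": self.raw})
        if self.normalized is not None:
            out["normalized"] = self.normalized
        if self.standardized is not None:
            out["standardized"] = self.standardized
        out.index.name = "sample_id"
        return out


@dataclass
class Cohort:
    """A case-control cohort: the per-woman phenotype table plus the genotype
    matrix over the same samples.

    ``phenotypes`` is indexed by sample id with columns ``outcome`` (1 = case),
    ``age``, ``centre`` and the raw ``*_cat`` category columns; downstream
    stages add ``age_bin``, encoded ``*_enc`` columns and PRS columns.
    """

    phenotypes: pd.DataFrame
    genotypes: GenotypeMatrix | None = None

    def __post_init__(self):
        df = self.phenotypes
        missing = [c for c in ("outcome", "age", "centre") if c not in df.columns]
        if missing:
            raise ConfigurationError(f"cohort phenotype table missing columns: {missing}")
        if not df["outcome"].isin((0, 1)).all():
            raise ConfigurationError("outcome must be 0 (control) / 1 (case)")
        if self.genotypes is not None:
            if not df.index.equals(self.genotypes.sample_ids):
                raise ConfigurationError(
                    "phenotype table and genotype matrix must cover identical samples "
                    "in identical order")

    @property
    def sample_ids(self) -> pd.Index:
        return self.phenotypes.index

    @property
    def outcome(self) -> pd.Series:
        return self.phenotypes["outcome"]

    @property
    def n_cases(self) -> int:
        return int(self.outcome.sum())

    @property
    def n_controls(self) -> int:
        return int((1 - self.outcome).sum())

    @property
    def control_ids(self) -> pd.Index:
        return self.phenotypes.index[self.outcome == 0]

    def subset(self, sample_ids) -> "Cohort":
        ids = list(sample_ids)
        gt = self.genotypes.subset_samples(ids) if self.genotypes is not None else None
        return Cohort(self.phenotypes.loc[ids].copy(), gt)
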