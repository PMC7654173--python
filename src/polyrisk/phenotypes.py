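"""Phenotype encoding: categorical risk factors to quantitative variables.

Each categorical factor (mammographic density, age at first delivery,
menopause status, age at menarche, family history) is mapped to a
quantitative variable by looking up the per-category odds ratio in an
external encoding table; the reference category maps to 1.0. Age is grouped
into the eight 5-year bins spanning 30-70 and enters models as the ordinal
bin index.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AGE_BIN_EDGES, AGE_BIN_LABELS, PhenotypeSpec
from .data import FACTORS, Cohort
from .errors import ConfigurationError, EncodingError


@dataclass(frozen=True)
class FactorEncoding:
    """Category -> odds-ratio lookup for one risk factor.

    ``ors`` maps every category label to its OR (> 0); ``reference`` is the
    category with OR 1.0 by definition.
    """

    factor: str
    ors: dict
    reference: str

    def __post_init__(self):
        if self.reference not in self.ors:
            raise ConfigurationError(
                f"factor '{self.factor}': reference category '{self.reference}' "
                f"missing from OR table")
        for cat, orv in self.ors.items():
            if not orv > 0:
                raise ConfigurationError(
                    f"factor '{self.factor}': OR for '{cat}' must be positive, got {orv}")
        if abs(self.ors[self.reference] - 1.0) > 1e-9:
            raise ConfigurationError(
                f"factor '{self.factor}': reference category OR must be 1.0")

    @property
    def categories(self) -> tuple:
        return tuple(self.ors)

    @classmethod
    def from_spec(cls, spec: PhenotypeSpec) -> "FactorEncoding":
        """Build the encoding implied by a simulation factor spec (OR =
        exp(generative log-OR); the first category is the reference)."""
        return cls(spec.name, dict(zip(spec.categories, spec.ors)), spec.categories[0])


def encode_factor(categories, encoding: FactorEncoding) -> pd.Series:
    """Map each woman's category label to its odds ratio.

    Raises :class:`EncodingError` naming the first label absent from the
    table. Missing values (NaN) also raise unless the table defines them as
    their own category.
    """
    cats = pd.Series(categories)
    values = cats.map(encoding.ors)
    unknown = values.isna() & ~cats.isin(encoding.ors)
    if unknown.any():
        bad = cats[unknown].iloc[0]
        raise EncodingError(
            f"factor '{encoding.factor}': no OR for category {bad!r}")
    return values.astype(float)


def bin_age(age):
    """Assign ages to 5-year bins [30,35), [35,40), ..., [65,70].

    Returns ``(index, label)`` for a scalar or ``(indices, labels)`` arrays
    for array input. Ages outside 30-70 are clamped with a warning; the
    cohort design covers ages 30-70 only.
    """
    arr = np.asarray(age, dtype=float)
    if np.isnan(arr).any():
        raise ConfigurationError("age contains non-numeric / missing values")
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if (arr < AGE_BIN_EDGES[0]).any() or (arr > AGE_BIN_EDGES[-1]).any():
        warnings.warn("ages outside 30-70 clamped to the boundary bins", stacklevel=2)
        arr = np.clip(arr, AGE_BIN_EDGES[0], AGE_BIN_EDGES[-1])
    # Half-open [lo, hi) bins; the top bin is closed at 70.
    idx = np.searchsorted(AGE_BIN_EDGES[1:-1], arr, side="right")
    labels = np.asarray(AGE_BIN_LABELS, dtype=object)[idx]
    if scalar:
        return int(idx[0]), str(labels[0])
    return idx.astype(int), labels


def validate_phenotypes(table: pd.DataFrame, exclude: bool = False):
    """Flag (or drop) rows with incomplete phenotype data.

    A value counts as missing when it is NaN/empty; categories explicitly
    defined as their own level (e.g. menarche "Null") are complete data and
    must be spelled out in the table. Returns ``(table, report)`` where the
    report lists flagged rows per column; with ``exclude=True`` flagged rows
    are dropped.
    """
    cat_cols = [f"{f}_cat" for f in FACTORS]
    cols = [c for c in ("outcome", "age", "centre", *cat_cols) if c in table.columns]
    missing_mask = table[cols].isna()
    if any(table[c].dtype == object for c in cat_cols if c in table.columns):
        for c in cat_cols:
            if c in table.columns:
                missing_mask[c] |= table[c].astype(str).str.strip().eq("")
    flagged = missing_mask.any(axis=1)
    report = {
        "n_rows": int(len(table)),
        "n_flagged": int(flagged.sum()),
        "flagged_ids": table.index[flagged].tolist(),
        "missing_by_column": {c: int(missing_mask[c].sum())
                              for c in cols if missing_mask[c].any()},
        "excluded": bool(exclude),
    }
    out = table.loc[~flagged].copy() if exclude else table.copy()
    return out, report


def encode_cohort(cohort: Cohort, encodings: dict[str, FactorEncoding]) -> Cohort:
    """Add ``age_bin`` and the quantitative ``*_enc`` columns to a cohort.

    ``encodings`` maps factor names (as in :data:`~polyrisk.data.FACTORS`)
    to their OR tables; every factor present in the table must be covered.
    """
    df = cohort.phenotypes.copy()
    idx, labels = bin_age(df["age"].to_numpy())
    df["age_bin"] = idx
    df["age_bin_label"] = labels
    for factor in FACTORS:
        col = f"{factor}_cat"
        if col not in df.columns:
            continue
        if factor not in encodings:
            raise ConfigurationError(f"no encoding table supplied for factor '{factor}'")
        df[f"{factor}_enc"] = encode_factor(df[col], encodings[factor]).to_numpy()
    return Cohort(df, cohort.genotypes)
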