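"""Readers and writers for the on-disk formats.

Formats: SNP panel TSV (rsid, effect_allele, other_allele, or, eaf, status),
dosage TSV (rows = samples, columns = rsids, empty cell = missing genotype),
phenotype CSV, factor-encoding TSV (factor, category, or_value,
is_reference) and VCF 4.2 (via pysam; the effect-allele count is derived
from GT against the panel's recorded effect allele, with strand resolution
limited to exact A/C/G/T complement flips).
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .data import PHENOTYPE_COLUMNS, Cohort, GenotypeMatrix, SNPPanel
from .errors import ConfigurationError, PanelError
from .phenotypes import FactorEncoding

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _comp(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in allele)


# ---------------------------------------------------------------- panel TSV

def write_panel_tsv(panel: SNPPanel, path) -> None:
    out = panel.table.rename(columns={"or_value": "or"})
    out.to_csv(path, sep="\t", index=False)


def read_panel_tsv(path) -> SNPPanel:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - message formatting only
        raise PanelError(f"malformed panel TSV {path}: {exc}") from exc
    if "or" in df.columns:
        df = df.rename(columns={"or": "or_value"})
    if "status" not in df.columns:
        df["status"] = "ok"
    return SNPPanel(df)


# --------------------------------------------------------------- dosage TSV

def write_dosage_tsv(gt: GenotypeMatrix, path) -> None:
    out = gt.dosages.copy()
    out.index.name = "sample_id"
    # integral dosages, empty cell for missing
    out.to_csv(path, sep="\t", float_format="%.0f", na_rep="")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return GenotypeMatrix(df.astype(float))


# ------------------------------------------------------------ phenotype CSV

def write_phenotype_csv(phenotypes: pd.DataFrame, path) -> None:
    out = phenotypes.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


def read_phenotype_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample_id")
    missing = [c for c in PHENOTYPE_COLUMNS
               if c != "sample_id" and c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"phenotype CSV {path} missing required column(s): {', '.join(missing)}")
    return df


# ------------------------------------------------------------- encoding TSV

def write_encoding_tsv(encodings: dict[str, FactorEncoding], path) -> None:
    rows = []
    for enc in encodings.values():
        for cat, orv in enc.ors.items():
            rows.append((enc.factor, cat, orv, int(cat == enc.reference)))
    pd.DataFrame(rows, columns=["factor", "category", "or_value", "is_reference"]) \
        .to_csv(path, sep="\t", index=False)


def read_encoding_tsv(path) -> dict[str, FactorEncoding]:
    df = pd.read_csv(path, sep="\t", dtype={"category": str})
    encodings = {}
    for factor, grp in df.groupby("factor", sort=False):
        refs = grp.loc[grp["is_reference"] == 1, "category"]
        if len(refs) != 1:
            raise ConfigurationError(
                f"encoding table {path}: factor '{factor}' must have exactly one "
                f"reference category, found {len(refs)}")
        encodings[factor] = FactorEncoding(
            factor, dict(zip(grp["category"], grp["or_value"].astype(float))),
            refs.iloc[0])
    return encodings


# --------------------------------------------------------------------- VCF

def write_vcf(gt: GenotypeMatrix, panel: SNPPanel, path) -> None:
    """One VCF record per panel SNP; REF = other allele, ALT = effect allele,
    GT = effect-allele count; missing calls written as ``./.``."""
    panel = panel.subset(gt.rsids)
    header = pysam.VariantHeader()
    header.contigs.add("1", length=max(2 * len(panel), 2))
    header.formats.add("GT", 1, "String", "Genotype")
    for s in gt.sample_ids:
        header.add_sample(str(s))
    dos = gt.dosages
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i, row in enumerate(panel.table.itertuples(index=False)):
            rec = vcf.new_record(contig="1", start=i, stop=i + 1,
                                 alleles=(row.other_allele, row.effect_allele),
                                 id=row.rsid)
            col = dos[row.rsid]
            for s in gt.sample_ids:
                d = col.loc[s]
                if np.isnan(d):
                    rec.samples[str(s)]["GT"] = (None, None)
                else:
                    d = int(d)
                    rec.samples[str(s)]["GT"] = ((0, 0), (0, 1), (1, 1))[d]
            vcf.write(rec)


def read_vcf(path, panel: SNPPanel) -> tuple[GenotypeMatrix, dict]:
    """Read effect-allele counts from a VCF against the panel's orientation.

    Records whose (REF, ALT) match (other, effect) count ALT alleles; the
    swapped orientation counts REF alleles; an exact complement flip of
    either orientation is resolved and logged. Ambiguous strand pairs
    (A/T or C/G SNPs) are flagged in the report because a complement flip is
    indistinguishable from an allele swap for them.
    """
    ptab = panel.table.set_index("rsid")
    columns, data = [], []
    report = {"flipped": [], "ambiguous": [], "skipped": []}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            rsid = rec.id
            if rsid not in ptab.index:
                report["skipped"].append(rsid)
                continue
            effect = ptab.at[rsid, "effect_allele"]
            other = ptab.at[rsid, "other_allele"]
            ref, alt = rec.ref, (rec.alts[0] if rec.alts else None)
            if {effect, other} == {_comp(effect), _comp(other)}:
                report["ambiguous"].append(rsid)
            if (ref, alt) == (other, effect):
                count_allele = 1
            elif (ref, alt) == (effect, other):
                count_allele = 0
            elif (ref, alt) == (_comp(other), _comp(effect)):
                count_allele = 1
                report["flipped"].append(rsid)
                log.info("VCF record %s resolved by strand complement flip", rsid)
            elif (ref, alt) == (_comp(effect), _comp(other)):
                count_allele = 0
                report["flipped"].append(rsid)
                log.info("VCF record %s resolved by strand complement flip", rsid)
            else:
                raise PanelError(
                    f"VCF record {rsid}: alleles {ref}/{alt} do not match panel "
                    f"{other}/{effect} or their complements")
            row = np.full(len(samples), np.nan)
            for j, s in enumerate(samples):
                gt_call = rec.samples[s]["GT"]
                if gt_call is None or any(a is None for a in gt_call):
                    continue
                row[j] = sum(1 for a in gt_call if a == count_allele)
            columns.append(rsid)
            data.append(row)
    dosages = pd.DataFrame(np.asarray(data).T if data else np.empty((len(samples), 0)),
                           index=pd.Index(samples, name="sample_id"), columns=columns)
    return GenotypeMatrix(dosages), report


# ------------------------------------------------------------- read_inputs

def read_inputs(panel_path, genotype_path, phenotype_path,
                genotype_format: str = "auto") -> tuple[SNPPanel, GenotypeMatrix, Cohort]:
    """Load and reconcile the three inputs of a real-data run.

    Sample ids present in only one of the genotype and phenotype tables are
    dropped (intersection), with counts logged; the genotype matrix is
    restricted to panel SNPs.
    """
    panel = read_panel_tsv(panel_path)
    genotype_path = Path(genotype_path)
    if genotype_format == "auto":
        genotype_format = "vcf" if genotype_path.suffix.lower() == ".vcf" else "tsv"
    if genotype_format == "vcf":
        gt, _report = read_vcf(genotype_path, panel)
    else:
        gt = read_dosage_tsv(genotype_path)
    phen = read_phenotype_csv(phenotype_path)

    shared = gt.sample_ids.intersection(phen.index)
    n_gt_only = len(gt.sample_ids.difference(phen.index))
    n_ph_only = len(phen.index.difference(gt.sample_ids))
    if len(shared) == 0:
        raise ConfigurationError(
            f"no shared sample ids between {genotype_path} and {phenotype_path}")
    if n_gt_only or n_ph_only:
        log.warning("sample id reconciliation: %d genotype-only and %d phenotype-only "
                    "samples dropped; %d retained", n_gt_only, n_ph_only, len(shared))
    shared = [s for s in phen.index if s in set(shared)]  # keep phenotype order
    gt = gt.subset_samples(shared)
    keep_snps = [r for r in gt.rsids if r in set(panel.rsids)]
    gt = gt.subset_snps(keep_snps)
    cohort = Cohort(phen.loc[shared].copy(), gt)
    return panel, gt, cohort
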