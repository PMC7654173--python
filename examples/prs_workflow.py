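"""Panel filtering, genotype QC and the polygenic risk score.

Starts from a 123-SNP candidate panel containing 28 near-null SNPs
(0.95 < OR < 1.05) and 3 genotyping failures, filters it down to the 92
scoring SNPs, computes the PRS on its three scales and estimates the odds
ratio per control SD, adjusted for age bin and five genotype principal
components.
"""
import polyrisk as pr
from polyrisk.phenotypes import FactorEncoding

config = pr.SimulationConfig(n_snps=123, n_near_null=28, n_failed=3, seed=3)
panel = pr.generate_snp_panel(config)
retained, removal_log = pr.filter_snp_panel(panel)
print(f"panel: {len(panel)} candidate SNPs -> {len(retained)} retained "
      f"({(removal_log['reason'] == 'near_null').sum()} near-null, "
      f"{(removal_log['reason'] == 'genotyping_failure').sum()} failed)")

_, cohort = pr.simulate_cohort(config)
gt = cohort.genotypes.subset_snps(retained.rsids)
gt, dropped_samples = pr.qc_samples(gt)           # call rate >= 0.95
gt, dropped_snps = pr.qc_snps(gt, panel=retained)  # genotyping rate >= 0.95
print(f"QC: {len(dropped_samples)} samples and {len(dropped_snps)} SNPs dropped")

raw = pr.compute_prs(gt, retained.subset(gt.rsids))
prs = pr.normalize_prs(raw, cohort.control_ids)
print(f"control-median-normalized PRS of first woman: {prs.normalized.iloc[0]:.3f}")

pcs = pr.genotype_pcs(gt, k=5)
encodings = {s.name: FactorEncoding.from_spec(s) for s in config.phenotype_specs}
cohort = pr.encode_cohort(pr.Cohort(cohort.phenotypes, gt), encodings)
fit = pr.prs_association(cohort.phenotypes, prs, pcs)
print(f"OR per SD of PRS: {fit.or_per_unit:.2f} "
      f"(95% CI {fit.ci_low:.2f}-{fit.ci_high:.2f}, p={fit.p_value:.2g})")

# The OR per SD says how much the odds of being a case multiply for each
# control-standard-deviation increase of the score; values around 1.3-1.6
# are typical of breast-cancer PRS panels of this size.
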