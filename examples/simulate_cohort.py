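"""Generate a synthetic case-control cohort and write it to disk.

The generator draws a prospective population (SNP genotypes under
Hardy-Weinberg equilibrium, categorical risk factors at their control
frequencies, a logistic disease model) and then retrospectively samples a
fixed number of cases and controls, the way a case-control study recruits.
"""
import polyrisk as pr

config = pr.SimulationConfig(n_snps=92, n_cases=455, n_controls=642, seed=1)
panel, cohort = pr.simulate_cohort(config)
paths = pr.write_fixture(cohort, panel, "scratch/example_cohort")

print(f"panel SNPs:        {len(panel)}")
print(f"cohort:            {cohort.n_cases} cases / {cohort.n_controls} controls")
print(f"median control age:{cohort.phenotypes.loc[cohort.control_ids, 'age'].median():>6.1f}")
for name, path in paths.items():
    print(f"  wrote {name}: {path}")

# The counts mirror the emulated study design (455/642, 92 SNPs); ages and
# category frequencies follow the control column of the design's Table-1-style
# layout, so downstream stages see realistic marginals.
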