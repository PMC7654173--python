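"""Synthetic cohort generator: panel construction, HWE, the disease model
and retrospective ascertainment."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import logit

import polyrisk as pr
from polyrisk.errors import AscertainmentError, ConfigurationError

from conftest import make_panel


def null_effect_config(**kw):
    """All phenotype and genotype effects zero."""
    import dataclasses
    specs = tuple(dataclasses.replace(s, log_ors=tuple(0.0 for _ in s.log_ors))
                  for s in pr.default_phenotype_specs())
    defaults = dict(phenotype_specs=specs, per_allele_log_or=None, seed=1)
    defaults.update(kw)
    return pr.SimulationConfig(**defaults)


class TestGenerateSnpPanel:
    def test_default_panel_has_no_near_null_ors(self):
        panel = pr.generate_snp_panel(pr.SimulationConfig(n_snps=92, seed=1))
        assert len(panel) == 92
        assert not ((panel.or_values > 0.95) & (panel.or_values < 1.05)).any()

    def test_injected_composition(self):
        cfg = pr.SimulationConfig(n_snps=123, n_near_null=28, n_failed=3, seed=2)
        panel = pr.generate_snp_panel(cfg)
        near = (panel.or_values > 0.95) & (panel.or_values < 1.05)
        assert near.sum() == 28
        assert (panel.table["status"] == "genotyping_failure").sum() == 3
        # flags and near-null draws coincide
        assert (panel.table.loc[near, "status"] == "near_null").all()

    def test_same_config_same_panel(self):
        cfg = pr.SimulationConfig(n_snps=40, n_near_null=5, seed=9)
        pd.testing.assert_frame_equal(pr.generate_snp_panel(cfg).table,
                                      pr.generate_snp_panel(cfg).table)

    def test_invalid_maf_range_rejected(self):
        with pytest.raises(ConfigurationError):
            pr.SimulationConfig(maf_range=(0.0, 0.6))


class TestSimulatePopulation:
    def test_null_model_prevalence_matches_baseline(self):
        n = 50_000
        cfg = null_effect_config(baseline_log_odds=float(logit(0.12)),
                                 per_allele_log_or=(0.0,) * 92)
        panel = pr.generate_snp_panel(cfg)
        pop = pr.simulate_population(panel, cfg, n)
        frac = pop.outcome.mean()
        se = math.sqrt(0.12 * 0.88 / n)
        assert abs(frac - 0.12) < 3 * se

    def test_hwe_genotype_frequencies(self):
        """Control genotype counts follow Binomial(2, MAF) within 4 SE."""
        panel = make_panel([1.0], eaf=[0.3])
        cfg = null_effect_config(n_snps=1, per_allele_log_or=(0.0,))
        n = 20_000
        pop = pr.simulate_population(panel, cfg, n)
        x = pop.genotypes.dosages.iloc[:, 0].to_numpy()
        expected = {0: 0.49, 1: 0.42, 2: 0.09}
        for g, p in expected.items():
            obs = (x == g).mean()
            se = math.sqrt(p * (1 - p) / n)
            assert abs(obs - p) < 4 * se, f"genotype {g}: {obs} vs {p}"

    def test_single_snp_effect_recovery_coverage(self):
        """Logistic fit on the prospective population covers the injected
        per-allele log-OR in >= 90% of replicates."""
        import statsmodels.api as sm
        true_beta = math.log(2.0)
        covered = 0
        reps = 60
        for rep in range(reps):
            panel = make_panel([2.0], eaf=[0.3])
            cfg = null_effect_config(n_snps=1, per_allele_log_or=(true_beta,),
                                     seed=1000 + rep)
            pop = pr.simulate_population(panel, cfg, 20_000)
            x = pop.genotypes.dosages.iloc[:, 0].to_numpy()
            X = sm.add_constant(x)
            res = sm.Logit(pop.outcome.to_numpy(), X).fit(disp=0)
            lo, hi = res.conf_int()[1]
            covered += lo <= true_beta <= hi
        assert covered / reps >= 0.90

    def test_determinism(self):
        cfg = null_effect_config(n_snps=5, seed=3)
        panel = pr.generate_snp_panel(cfg)
        a = pr.simulate_population(panel, cfg, 500)
        b = pr.simulate_population(panel, cfg, 500)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        pd.testing.assert_frame_equal(a.genotypes.dosages, b.genotypes.dosages)


class TestAscertainment:
    def test_exact_counts(self):
        cfg = null_effect_config(n_snps=3, seed=5)
        panel = pr.generate_snp_panel(cfg)
        pop = pr.simulate_population(panel, cfg, 12_000)
        cohort = pr.ascertain_case_control(pop, 455, 642, seed=5)
        assert cohort.n_cases == 455 and cohort.n_controls == 642
        assert len(cohort.phenotypes) == 1097

    def test_shortfall_raises_named_error(self):
        cfg = null_effect_config(n_snps=2, seed=6)
        panel = pr.generate_snp_panel(cfg)
        pop = pr.simulate_population(panel, cfg, 200)
        with pytest.raises(AscertainmentError, match="short by"):
            pr.ascertain_case_control(pop, 1000, 10, seed=0)

    def test_ascertainment_preserves_odds_ratio(self):
        """Mean estimated per-allele log-OR over ascertained cohorts matches
        the generative truth (retrospective sampling preserves ORs)."""
        import statsmodels.api as sm
        true_beta = 0.4
        estimates = []
        for rep in range(100):
            panel = make_panel([math.exp(true_beta)], eaf=[0.3])
            cfg = null_effect_config(n_snps=1, per_allele_log_or=(true_beta,),
                                     seed=2000 + rep)
            pop = pr.simulate_population(panel, cfg, 4_000)
            cohort = pr.ascertain_case_control(pop, 200, 280, seed=rep)
            x = cohort.genotypes.dosages.iloc[:, 0].to_numpy()
            res = sm.Logit(cohort.outcome.to_numpy(), sm.add_constant(x)).fit(disp=0)
            estimates.append(res.params[1])
        mean = np.mean(estimates)
        sem = np.std(estimates, ddof=1) / math.sqrt(len(estimates))
        assert abs(mean - true_beta) < 4 * sem + 0.02


class TestFixtureRoundTrip:
    def test_write_then_read_recovers_cohort(self, small_cohort, tmp_path):
        from polyrisk import io as pio
        panel, cohort = small_cohort
        paths = pr.write_fixture(cohort, panel, tmp_path)
        panel2, gt2, cohort2 = pio.read_inputs(paths["panel"], paths["vcf"],
                                               paths["phenotypes"])
        assert list(panel2.rsids) == list(panel.rsids)
        np.testing.assert_allclose(panel2.or_values, panel.or_values, rtol=1e-9)
        np.testing.assert_array_equal(
            gt2.dosages[list(cohort.genotypes.rsids)].to_numpy(),
            cohort.genotypes.dosages.to_numpy())
        pd.testing.assert_series_equal(cohort2.outcome, cohort.outcome)
        # dosage TSV route agrees with the VCF route
        gt3 = pio.read_dosage_tsv(paths["dosages"])
        np.testing.assert_array_equal(gt3.dosages.to_numpy(),
                                      cohort.genotypes.dosages.to_numpy())

    def test_vcf_one_record_per_snp_and_missing_encoding(self, small_cohort, tmp_path):
        panel, cohort = small_cohort
        cohort = cohort.subset(cohort.sample_ids[:5])
        dos = cohort.genotypes.dosages.copy()
        dos.iloc[0, 0] = np.nan
        cohort = pr.Cohort(cohort.phenotypes, pr.GenotypeMatrix(dos))
        paths = pr.write_fixture(cohort, panel, tmp_path)
        vcf_lines = [l for l in paths["vcf"].read_text().splitlines()
                     if l and not l.startswith("#")]
        assert len(vcf_lines) == len(panel)
        assert "./." in vcf_lines[0]
        # empty cell in the TSV for the same call
        tsv_first_row = paths["dosages"].read_text().splitlines()[1]
        assert tsv_first_row.split("\t")[1] == ""
        from polyrisk import io as pio
        gt2, _ = pio.read_vcf(paths["vcf"], panel)
        assert np.isnan(gt2.dosages.loc[cohort.sample_ids[0], panel.rsids[0]])
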