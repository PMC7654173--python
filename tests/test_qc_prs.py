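"""Panel filtering, call-rate QC, PRS arithmetic and genotype PCs."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import polyrisk as pr
from polyrisk.errors import ConfigurationError, MissingSNPError, PanelError, QCError

from conftest import make_genotypes, make_panel


class TestFilterSnpPanel:
    def test_study_composition_retains_92(self):
        cfg = pr.SimulationConfig(n_snps=123, n_near_null=28, n_failed=3, seed=4)
        panel = pr.generate_snp_panel(cfg)
        retained, log = pr.filter_snp_panel(panel)
        assert len(retained) == 92
        assert len(log) == 31
        assert set(log["reason"]) == {"near_null", "genotyping_failure"}

    def test_boundary_or_exactly_095_retained(self):
        panel = make_panel([0.95, 1.05, 0.949, 1.051, 0.96])
        retained, log = pr.filter_snp_panel(panel)
        # strict inequality: the window endpoints stay in
        assert list(retained.table["rsid"]) == ["rs0", "rs1", "rs2", "rs3"]
        assert list(log["rsid"]) == ["rs4"]

    def test_all_ok_panel_unchanged(self):
        panel = make_panel([1.3, 0.8, 1.5])
        retained, log = pr.filter_snp_panel(panel)
        pd.testing.assert_frame_equal(retained.table, panel.table)
        assert log.empty

    def test_emptied_panel_raises(self):
        with pytest.raises(PanelError):
            pr.filter_snp_panel(make_panel([1.0, 1.01]))

    @given(n_near=st.integers(0, 10), n_fail=st.integers(0, 5))
    def test_retained_count_arithmetic(self, n_near, n_fail):
        """retained = total - near_null - failed for disjoint injections."""
        total = 30
        cfg = pr.SimulationConfig(n_snps=total, n_near_null=n_near,
                                  n_failed=n_fail, seed=17)
        retained, _ = pr.filter_snp_panel(pr.generate_snp_panel(cfg))
        assert len(retained) == total - n_near - n_fail


class TestCallRateQC:
    def _matrix_with_missing(self, n_missing, n_snps=92):
        arr = np.ones((3, n_snps))
        arr[0, :n_missing] = np.nan
        return make_genotypes(arr)

    def test_sample_below_threshold_dropped(self):
        # 87/92 calls = 0.9457 < 0.95
        gt = self._matrix_with_missing(5)
        kept, dropped = pr.qc_samples(gt)
        assert list(dropped["sample_id"]) == ["S0"]
        assert kept.n_samples == 2

    def test_sample_above_threshold_kept(self):
        # 88/92 calls = 0.9565 >= 0.95
        gt = self._matrix_with_missing(4)
        kept, dropped = pr.qc_samples(gt)
        assert dropped.empty and kept.n_samples == 3

    def test_snp_low_rate_and_duplicate_flag_dropped(self):
        arr = np.ones((50, 3))
        arr[:3, 0] = np.nan  # 47/50 = 0.94
        gt = make_genotypes(arr)
        panel = make_panel([1.2, 1.3, 1.4], status=["ok", "duplicate_error", "ok"])
        kept, dropped = pr.qc_snps(gt, panel=panel)
        assert set(dropped["rsid"]) == {"rs0", "rs1"}
        assert dict(zip(dropped["rsid"], dropped["reason"])) == {
            "rs0": "low_call_rate", "rs1": "duplicate_error"}
        assert list(kept.rsids) == ["rs2"]

    def test_qc_idempotent_and_identity_on_clean_data(self):
        gt = make_genotypes(np.ones((4, 6)))
        once, _ = pr.qc_samples(gt)
        twice, _ = pr.qc_samples(once)
        pd.testing.assert_frame_equal(once.dosages, gt.dosages)
        pd.testing.assert_frame_equal(twice.dosages, once.dosages)
        once_s, _ = pr.qc_snps(gt)
        pd.testing.assert_frame_equal(once_s.dosages, gt.dosages)

    def test_all_dropped_raises(self):
        gt = make_genotypes(np.full((2, 4), np.nan))
        with pytest.raises(QCError):
            pr.qc_samples(gt)


class TestComputePrs:
    def test_zero_genotypes_zero_score(self):
        gt = make_genotypes(np.zeros((3, 4)))
        raw = pr.compute_prs(gt, make_panel([1.2, 1.5, 0.8, 2.0]))
        assert (raw == 0).all()

    def test_single_snp_arithmetic(self):
        gt = make_genotypes([[2.0]])
        raw = pr.compute_prs(gt, make_panel([2.0]))
        assert raw.iloc[0] == pytest.approx(2 * math.log(2), abs=1e-12)

    def test_or_weight_switch(self):
        gt = make_genotypes([[2.0]])
        raw = pr.compute_prs(gt, make_panel([2.0]), weights="or")
        assert raw.iloc[0] == pytest.approx(4.0, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_double_loop_oracle(self, seed):
        """Vectorised score equals naive per-sample accumulation."""
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 3, size=(10, 8)).astype(float)
        ors = rng.uniform(0.5, 2.5, size=8)
        gt, panel = make_genotypes(x), make_panel(list(ors))
        raw = pr.compute_prs(gt, panel)
        for i in range(10):
            acc = 0.0
            for k in range(8):
                acc += math.log(ors[k]) * x[i, k]
            assert raw.iloc[i] == pytest.approx(acc, abs=1e-12)

    def test_additivity_over_disjoint_panels(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, size=(6, 10)).astype(float)
        ors = rng.uniform(0.5, 2.0, size=10)
        gt = make_genotypes(x)
        full = pr.compute_prs(gt, make_panel(list(ors)))
        pa = pr.SNPPanel(make_panel(list(ors)).table.iloc[:4])
        pb = pr.SNPPanel(make_panel(list(ors)).table.iloc[4:])
        np.testing.assert_allclose(full, pr.compute_prs(gt, pa) + pr.compute_prs(gt, pb),
                                   atol=1e-12)

    def test_missing_expected_dosage_imputation(self):
        x = np.array([[np.nan, 2.0]])
        panel = make_panel([2.0, 1.5], eaf=[0.25, 0.3])
        raw = pr.compute_prs(make_genotypes(x), panel)
        expected = math.log(2.0) * (2 * 0.25) + math.log(1.5) * 2
        assert raw.iloc[0] == pytest.approx(expected, abs=1e-12)
        raw0 = pr.compute_prs(make_genotypes(x), panel, missing_policy="zero")
        assert raw0.iloc[0] == pytest.approx(math.log(1.5) * 2, abs=1e-12)

    def test_absent_snp_raises_with_names(self):
        gt = make_genotypes(np.ones((2, 1)), rsids=["rsX"])
        with pytest.raises(MissingSNPError, match="rs0"):
            pr.compute_prs(gt, make_panel([1.2]))


class TestNormalizePrs:
    def test_median_and_sd_scales(self):
        raw = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        res = pr.normalize_prs(raw, ["a", "b", "c"])
        np.testing.assert_allclose(res.normalized, [0.5, 1.0, 1.5])
        assert res.standardized.mean() == pytest.approx(0, abs=1e-12)
        assert res.standardized.std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(1)
        raw = pd.Series(rng.normal(5, 1, 50))
        res = pr.normalize_prs(raw, raw.index[:30])
        assert (res.normalized.rank() == raw.rank()).all()
        assert (res.standardized.rank() == raw.rank()).all()

    def test_zero_median_directs_to_standardized(self):
        raw = pd.Series([-1.0, 0.0, 1.0])
        with pytest.raises(ConfigurationError, match="standardized"):
            pr.normalize_prs(raw, raw.index)


class TestGenotypePcs:
    def test_orthogonal_centered_coordinates(self):
        rng = np.random.default_rng(2)
        gt = make_genotypes(rng.integers(0, 3, size=(40, 20)).astype(float))
        pcs = pr.genotype_pcs(gt, k=5)
        centered = pcs.to_numpy() - pcs.to_numpy().mean(axis=0)
        gram = centered.T @ centered
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_pc1_separates_divergent_subpopulations(self):
        rng = np.random.default_rng(3)
        a = rng.binomial(2, 0.1, size=(60, 30)).astype(float)
        b = rng.binomial(2, 0.5, size=(60, 30)).astype(float)
        gt = make_genotypes(np.vstack([a, b]))
        pcs = pr.genotype_pcs(gt, k=2)
        label = np.r_[np.zeros(60), np.ones(60)]
        r = np.corrcoef(pcs["PC1"], label)[0, 1]
        assert abs(r) > 0.9

    def test_duplicated_cohort_duplicates_coordinates(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 3, size=(15, 10)).astype(float)
        pcs1 = pr.genotype_pcs(make_genotypes(x), k=3)
        dup = np.vstack([x, x])
        pcs2 = pr.genotype_pcs(make_genotypes(dup), k=3)
        np.testing.assert_allclose(np.abs(pcs2.to_numpy()[:15]),
                                   np.abs(pcs2.to_numpy()[15:]), atol=1e-8)

    def test_k_beyond_rank_raises(self):
        gt = make_genotypes(np.array([[0, 1], [1, 0], [2, 1.0]]))
        with pytest.raises(ConfigurationError):
            pr.genotype_pcs(gt, k=3)
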