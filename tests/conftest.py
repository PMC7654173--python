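import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import polyrisk as pr
from polyrisk.phenotypes import FactorEncoding

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    return pr.SimulationConfig(n_snps=12, n_cases=60, n_controls=80, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """(panel, cohort) with 12 SNPs and 140 women; session-scoped, read-only."""
    return pr.simulate_cohort(small_config)


def encoded_cohort(config):
    """Simulate, score and encode a cohort ready for association/model fits."""
    panel, cohort = pr.simulate_cohort(config)
    encodings = {s.name: FactorEncoding.from_spec(s) for s in config.phenotype_specs}
    cohort = pr.encode_cohort(cohort, encodings)
    raw = pr.compute_prs(cohort.genotypes, panel)
    prs = pr.normalize_prs(raw, cohort.control_ids)
    df = cohort.phenotypes
    df["prs_std"] = prs.standardized
    df["prs_normalized"] = prs.normalized
    return panel, pr.Cohort(df, cohort.genotypes)


@pytest.fixture(scope="session")
def study_cohort():
    """An encoded cohort at the design's size: 455 cases / 642 controls."""
    return encoded_cohort(pr.SimulationConfig(seed=11))


def make_panel(or_values, eaf=None, status=None):
    """Hand-built panel for unit tests."""
    n = len(or_values)
    eaf = [0.3] * n if eaf is None else eaf
    status = ["ok"] * n if status is None else status
    return pr.SNPPanel(pd.DataFrame({
        "rsid": [f"rs{i}" for i in range(n)],
        "effect_allele": ["A"] * n,
        "other_allele": ["G"] * n,
        "or_value": or_values,
        "eaf": eaf,
        "status": status,
    }))


def make_genotypes(array, rsids=None):
    arr = np.asarray(array, float)
    rsids = [f"rs{i}" for i in range(arr.shape[1])] if rsids is None else rsids
    idx = pd.Index([f"S{i}" for i in range(arr.shape[0])], name="sample_id")
    return pr.GenotypeMatrix(pd.DataFrame(arr, index=idx, columns=rsids))
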