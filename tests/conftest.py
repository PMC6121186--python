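import numpy as np
import pandas as pd
import pytest

from methylmr import CohortData, ScenarioConfig, simulate_region


@pytest.fixture(scope="session")
def mediation_region():
    cfg = ScenarioConfig(scenario="mediation", seed=42)
    return simulate_region(cfg)


@pytest.fixture(scope="session")
def linkage_region():
    cfg = ScenarioConfig(scenario="linkage", seed=43)
    return simulate_region(cfg)


@pytest.fixture(scope="session")
def null_region():
    cfg = ScenarioConfig(scenario="null", seed=44)
    return simulate_region(cfg)


def make_cohort(dosages, meth=None, positions=None, chrom="1", eaf=None, phenotype=None):
    """Hand-built cohort for small deterministic fixtures."""
    dosages = np.asarray(dosages, dtype=float)
    m, n = dosages.shape
    if meth is None:
        meth = np.zeros((1, n))
    meth = np.atleast_2d(np.asarray(meth, dtype=float))
    if positions is None:
        positions = 1_000_000 + 1_000 * np.arange(m)
    if eaf is None:
        eaf = dosages.mean(axis=1) / 2.0
    pairs = [("A", "G"), ("T", "C"), ("A", "C"), ("T", "G"), ("G", "A"), ("C", "T")]
    snps = pd.DataFrame(
        {
            "SNP": [f"snp{j:02d}" for j in range(m)],
            "CHR": chrom,
            "POS": positions,
            "EA": [pairs[j % 6][0] for j in range(m)],
            "OA": [pairs[j % 6][1] for j in range(m)],
            "EAF": eaf,
        }
    )
    cpgs = pd.DataFrame(
        {
            "CPG": [f"cg{j:02d}" for j in range(len(meth))],
            "CHR": chrom,
            "POS": [int(positions[0]) + 100 * (j + 1) for j in range(len(meth))],
            "CLASS": ["island"] * len(meth),
        }
    )
    return CohortData(
        sample_ids=[f"s{j}" for j in range(n)],
        snps=snps,
        dosages=dosages,
        cpgs=cpgs,
        methylation=meth,
        phenotype=phenotype,
    )
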