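import numpy as np
import pandas as pd
import pytest

import mismatchprs as mp


@pytest.fixture(scope="session")
def small_cohort() -> mp.PairedCohort:
    """80-pair, 200-SNP mixed-relationship cohort used across modules."""
    cfg = mp.SimConfig(n_pairs=80, n_snps=200, seed=11)
    return mp.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_mismatch(small_cohort) -> mp.MismatchMatrix:
    return mp.mismatch_matrix(small_cohort)


@pytest.fixture(scope="session")
def null_scan_cohort() -> mp.PairedCohort:
    """Medium cohort with no causal SNPs for scan-level checks."""
    cfg = mp.SimConfig(n_pairs=300, n_snps=400, seed=21)
    return mp.simulate_cohort(cfg)


def toy_cohort(donor, recipient, chrom=None, pos=None, a0=None, a1=None, pheno=None):
    """Hand-built cohort from explicit dosage matrices."""
    donor = np.asarray(donor, float)
    n, m = donor.shape
    snps = mp.make_snp_table(
        snp_id=[f"s{j}" for j in range(m)],
        chrom=chrom or ["1"] * m,
        pos=pos or list(range(100, 100 + m)),
        a0=a0 or ["G"] * m,
        a1=a1 or ["A"] * m,
        alt_freq=np.nanmean(np.concatenate([donor, np.asarray(recipient, float)]), axis=0) / 2,
    )
    if pheno is None:
        rng = np.random.default_rng(0)
        pheno = pd.DataFrame(
            {
                "time_days": rng.integers(30, 400, n).astype(float),
                "event": rng.integers(0, 2, n),
                "recipient_age": rng.normal(50, 10, n),
                "recipient_male": rng.integers(0, 2, n),
                "pra_positive": rng.integers(0, 2, n),
                "hla_mismatch": rng.integers(0, 7, n),
                "prior_nonkidney_tx": rng.integers(0, 2, n),
            }
        )
    return mp.PairedCohort(
        pair_ids=np.array([f"P{i}" for i in range(n)]),
        donor=donor,
        recipient=np.asarray(recipient, float),
        snps=snps,
        phenotype=pheno,
    )
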