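"""Mismatch scoring, QC filters, HLA masking, and kinship estimation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mismatchprs as mp
from mismatchprs.mismatch_qc import QCThresholds

from conftest import toy_cohort


def test_ibs_mismatch_equals_brute_force_on_hard_calls():
    """|D - R| over all 9 hard-call genotype combinations."""
    for d, r in itertools.product((0, 1, 2), repeat=2):
        assert mp.ibs_mismatch(d, r) == abs(d - r)


def test_ibs_mismatch_symmetric_and_bounded():
    rng = np.random.default_rng(0)
    d = rng.uniform(0, 2, 200)
    r = rng.uniform(0, 2, 200)
    a = np.asarray(mp.ibs_mismatch(d, r, mode="dosage"))
    b = np.asarray(mp.ibs_mismatch(r, d, mode="dosage"))
    np.testing.assert_array_equal(a, b)
    assert np.nanmin(a) >= 0 and np.nanmax(a) <= 2


def test_hard_call_rounding_and_missing():
    assert mp.ibs_mismatch(1.95, 1.02, mode="hard_call", hard_call_tolerance=0.1) == 1.0
    assert np.isnan(mp.ibs_mismatch(1.5, 0.0, mode="hard_call", hard_call_tolerance=0.1))
    assert np.isnan(mp.ibs_mismatch(np.nan, 1.0))
    # dosage mode keeps fractions
    assert mp.ibs_mismatch(1.95, 1.02, mode="dosage") == pytest.approx(0.93)


@given(
    d=st.floats(min_value=0, max_value=2),
    r=st.floats(min_value=0, max_value=2),
    tol=st.floats(min_value=0, max_value=0.49),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_hard_call_mode_matches_rounding_oracle(d, r, tol):
    """hard_call scoring equals |round(D)-round(R)| whenever both round cleanly."""
    got = mp.ibs_mismatch(d, r, mode="hard_call", hard_call_tolerance=tol)
    d_ok = abs(d - round(d)) <= tol + 1e-12
    r_ok = abs(r - round(r)) <= tol + 1e-12
    if d_ok and r_ok:
        assert got == abs(round(d) - round(r))
    else:
        assert np.isnan(got)


def test_dosage_out_of_range_fails():
    with pytest.raises(ValueError, match="donor"):
        mp.ibs_mismatch(2.5, 1.0)


def test_mismatch_matrix_identity_pairing():
    g = np.random.default_rng(1).integers(0, 3, (4, 6)).astype(float)
    mm = mp.mismatch_matrix(toy_cohort(g, g))
    assert (mm.scores == 0).all()
    assert (mm.mean_mismatch == 0).all()


def test_mismatch_matrix_worked_grid():
    mm = mp.mismatch_matrix(toy_cohort([[0, 1], [2, 2]], [[2, 1], [1, 0]]))
    np.testing.assert_array_equal(mm.scores, [[2, 0], [1, 2]])
    np.testing.assert_array_equal(mm.mean_mismatch, [1.5, 1.0])


def test_mean_mismatch_recomputable_from_scores(small_mismatch):
    np.testing.assert_allclose(
        np.nanmean(small_mismatch.scores, axis=0), small_mismatch.mean_mismatch, atol=1e-9
    )


def test_expected_mismatch_hwe_closed_form():
    def enumeration(q):
        probs = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
        return sum(
            probs[d] * probs[r] * abs(d - r) for d in range(3) for r in range(3)
        )

    assert mp.expected_mismatch_hwe(0.0) == 0.0
    assert mp.expected_mismatch_hwe(0.5) == pytest.approx(0.75)
    for q in (0.073, 0.2, 0.9):
        assert mp.expected_mismatch_hwe(q) == pytest.approx(enumeration(q), abs=1e-12)
    with pytest.raises(ValueError):
        mp.expected_mismatch_hwe(1.2)


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------


def _qc_cohort():
    """Four-SNP cohort hitting each exclusion reason plus one clean SNP."""
    rng = np.random.default_rng(2)
    n = 40
    donor = np.column_stack(
        [
            rng.binomial(2, 0.96, n),  # MAF 0.04
            rng.binomial(2, 0.3, n),  # mean mismatch forced ~0 below
            rng.binomial(2, 0.3, n),  # high missingness below
            rng.binomial(2, 0.3, n),  # low info below
            rng.binomial(2, 0.3, n),  # clean
        ]
    ).astype(float)
    recipient = donor.copy()
    for j in (0, 2, 3, 4):  # give most SNPs informative mismatch
        recipient[:, j] = rng.binomial(2, [0.96, 0, 0.3, 0.3, 0.3][j], n)
    recipient[: n // 2, 2] = np.nan
    cohort = toy_cohort(donor, recipient)
    cohort.snps.loc[3, "imputation_info"] = 0.5
    cohort.snps.loc[4, "imputation_info"] = 0.99
    return cohort


def test_snp_qc_filter_reasons_in_fixed_order():
    cohort = _qc_cohort()
    mm = mp.mismatch_matrix(cohort)
    retained, report = mp.snp_qc_filter(cohort, mm)
    reasons = dict(zip(report["snp_id"], report["reason"]))
    assert reasons["s0"] == "maf"
    assert reasons["s1"] == "mismatch"
    assert reasons["s2"] == "missing"
    assert reasons["s3"] == "info"
    assert retained == ["s4"]
    assert "mean IBS mismatch" in report.attrs["thresholds"]["mismatch_filter_interpretation"]


def test_snp_qc_filter_order_independent():
    cohort = _qc_cohort()
    mm = mp.mismatch_matrix(cohort)
    retained, _ = mp.snp_qc_filter(cohort, mm)
    perm = np.array([4, 2, 0, 3, 1])
    shuffled = cohort.subset_snps(perm)
    retained_p, _ = mp.snp_qc_filter(shuffled, mp.mismatch_matrix(shuffled))
    assert set(retained_p) == set(retained)


def test_missing_info_treated_as_genotyped():
    cohort = toy_cohort([[0, 1], [2, 1], [1, 0]], [[2, 0], [0, 1], [1, 2]])
    assert cohort.snps["imputation_info"].isna().all()
    retained, report = mp.snp_qc_filter(cohort, mp.mismatch_matrix(cohort))
    assert "info" not in set(report["reason"])


# ---------------------------------------------------------------------------
# HLA mask
# ---------------------------------------------------------------------------


def test_hla_mask_inclusive_boundaries():
    snps = mp.make_snp_table(
        snp_id=["start", "below", "end", "above", "cps1", "other_chrom"],
        chrom=["6", "6", "6", "6", "2", "7"],
        pos=[25_759_242, 25_759_241, 33_534_827, 33_534_828, 211_541_165, 30_000_000],
        a0=["G"] * 6,
        a1=["A"] * 6,
    )
    hla, non_hla = mp.hla_mask(snps)
    assert set(hla) == {"start", "end"}
    assert set(non_hla) == {"below", "above", "cps1", "other_chrom"}
    assert len(hla) + len(non_hla) == len(snps)


def test_hla_mask_partitions_simulated_panel(small_cohort):
    hla, non_hla = mp.hla_mask(small_cohort.snps)
    assert len(hla) + len(non_hla) == small_cohort.n_snps
    assert set(hla).isdisjoint(non_hla)


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------


def test_kinship_of_identical_genotypes_is_half():
    rng = np.random.default_rng(3)
    g = rng.binomial(2, rng.uniform(0.1, 0.9, 3000), 3000).astype(float)
    assert mp.kinship(g, g) == pytest.approx(0.5)


def test_kinship_simulated_relationships():
    rng = np.random.default_rng(4)
    freqs = rng.uniform(0.1, 0.9, 5000)
    phis = {"parent_offspring": [], "unrelated": []}
    for rel in phis:
        for _ in range(40):
            d, r = mp.simulate_pair(rel, freqs, 0.0, 10, rng)
            phis[rel].append(mp.kinship(d, r))
    assert np.mean(phis["parent_offspring"]) == pytest.approx(0.25, abs=0.02)
    assert np.mean(phis["unrelated"]) == pytest.approx(0.0, abs=0.02)


def test_kinship_zero_denominator_returns_nan():
    d = np.zeros(2000)
    r = np.full(2000, 2.0)
    assert np.isnan(mp.kinship(d, r))


def test_cohort_kinship_ranks_relationships(small_cohort):
    phi = mp.cohort_kinship(small_cohort)
    rel = small_cohort.phenotype["relationship"].to_numpy()
    assert phi[rel == "parent_offspring"].mean() > phi[rel == "unrelated"].mean() + 0.15
    assert phi[rel == "full_sibling"].mean() > phi[rel == "unrelated"].mean() + 0.15


def test_qc_report_writer(tmp_path, small_cohort, small_mismatch):
    _, report = mp.snp_qc_filter(small_cohort, small_mismatch)
    from mismatchprs.mismatch_qc import write_qc_report

    write_qc_report(small_mismatch, report, str(tmp_path / "qc"))
    text = (tmp_path / "qc.exclusions.tsv").read_text()
    assert text.startswith("#")
    mismatch_tab = pd.read_csv(tmp_path / "qc.mismatch.tsv", sep="\t")
    assert len(mismatch_tab) == small_cohort.n_snps


def test_thresholds_validation():
    with pytest.raises(ValueError):
        QCThresholds(maf_min=1.5)
    with pytest.raises(ValueError):
        QCThresholds(hla_start=10, hla_end=5)
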