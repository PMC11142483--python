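"""Clumping, thresholding, PRS construction, scoring, validation, sensitivity."""

import numpy as np
import pandas as pd
import pytest

import mismatchprs as mp
from mismatchprs.prs_builder import squared_correlation
from mismatchprs.survival_scan import ScanResult


def _scan_from_frame(df) -> ScanResult:
    df = df.copy()
    for col, default in (
        ("a0", "G"),
        ("a1", "A"),
        ("a1_freq", 0.3),
        ("mean_mismatch", 0.3),
        ("se", 0.1),
        ("converged", True),
    ):
        if col not in df:
            df[col] = default
    if "hr" not in df:
        df["hr"] = np.exp(df["beta"]) if "beta" in df else 1.0
    if "beta" not in df:
        df["beta"] = 0.1
    return ScanResult(table=df, covariates=[], n_pairs=0, n_events=0, lambda_gc=1.0)


def _brute_force_clump(df, G, ids, r2_threshold, window_kb):
    """Oracle: naive greedy clumping recomputing every pairwise r-squared."""
    tab = df[np.isfinite(df["p"])].sort_values(["p", "pos", "snp_id"], kind="mergesort")
    col = {s: j for j, s in enumerate(ids)}
    remaining = list(tab.itertuples(index=False))
    out = []
    while remaining:
        head = remaining.pop(0)
        out.append(head.snp_id)
        survivors = []
        for row in remaining:
            same = str(row.chrom) == str(head.chrom)
            close = abs(row.pos - head.pos) <= window_kb * 1000
            r2 = (
                squared_correlation(G[:, col[head.snp_id]], G[:, col[row.snp_id]])
                if same and close
                else 0.0
            )
            if not (same and close and r2 >= r2_threshold):
                survivors.append(row)
        remaining = survivors
    return out


def test_clump_single_snp_is_its_own_index():
    df = pd.DataFrame({"snp_id": ["s0"], "chrom": ["1"], "pos": [100], "p": [0.01]})
    G = np.random.default_rng(0).integers(0, 3, (30, 1)).astype(float)
    assert mp.clump(_scan_from_frame(df), G, ["s0"]) == ["s0"]


def test_clump_window_rule_keeps_distant_correlated_snps():
    """Two SNPs 250 kb apart stay independent indices even at r2 = 0.9."""
    rng = np.random.default_rng(1)
    x = rng.normal(size=200)
    y = 0.97 * x + 0.24 * rng.normal(size=200)  # r2 ~ 0.94
    G = np.column_stack([x - x.min(), y - y.min()])
    G = 2 * (G - G.min()) / (G.max() - G.min())
    assert squared_correlation(G[:, 0], G[:, 1]) > 0.85
    df = pd.DataFrame(
        {"snp_id": ["s0", "s1"], "chrom": ["1", "1"], "pos": [100_000, 350_000], "p": [1e-5, 1e-4]}
    )
    assert mp.clump(_scan_from_frame(df), G, ["s0", "s1"]) == ["s0", "s1"]


def test_clump_removes_within_window_ld_partner():
    rng = np.random.default_rng(2)
    x = rng.integers(0, 3, 300).astype(float)
    df = pd.DataFrame(
        {"snp_id": ["s0", "s1"], "chrom": ["1", "1"], "pos": [100_000, 150_000], "p": [1e-5, 1e-4]}
    )
    assert mp.clump(_scan_from_frame(df), np.column_stack([x, x]), ["s0", "s1"]) == ["s0"]


def test_clump_matches_brute_force_oracle_on_ld_blocks():
    rng = np.random.default_rng(3)
    for instance in range(15):
        m = 50
        cfg = mp.SimConfig(n_pairs=80, n_snps=m, ld_rho=0.9, ld_block_size=5, seed=300 + instance)
        cohort = mp.simulate_cohort(cfg)
        G = cohort.recipient
        ids = list(cohort.snps["snp_id"])
        df = pd.DataFrame(
            {
                "snp_id": ids,
                "chrom": cohort.snps["chrom"].astype(str),
                "pos": cohort.snps["pos"],
                "p": rng.random(m),
            }
        )
        got = mp.clump(_scan_from_frame(df), G, ids, 0.2, 200.0)
        want = _brute_force_clump(df, G, ids, 0.2, 200.0)
        assert got == want


def test_clump_output_has_no_within_window_ld_pair(null_scan_cohort):
    cohort = null_scan_cohort
    mm = mp.mismatch_matrix(cohort)
    scan = mp.genome_scan(cohort, mm)
    ids = list(cohort.snps["snp_id"])
    indices = mp.clump(scan, cohort.recipient, ids)
    assert mp.check_clump_independence(indices, scan, cohort.recipient, ids)


def test_threshold_select_nested_and_trivial_cutoffs():
    rng = np.random.default_rng(4)
    m = 200
    df = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chrom": ["1"] * m,
            "pos": np.arange(m) * 1000 + 1,
            "p": rng.random(m) ** 2,
        }
    )
    scan = _scan_from_frame(df)
    ids = list(df["snp_id"])
    sets = mp.threshold_select(ids, scan, (1.0, 1e-1, 1e-2, 1e-3, 1e-12))
    assert sets[1.0] == ids  # cutoff 1 keeps everything
    assert sets[1e-12] == []  # below the minimum p
    assert set(sets[1e-3]) <= set(sets[1e-2]) <= set(sets[1e-1])


# ---------------------------------------------------------------------------
# Model construction and scoring
# ---------------------------------------------------------------------------


def _mismatch(scores, ids=None):
    scores = np.asarray(scores, float)
    return mp.MismatchMatrix(
        pair_ids=np.array([f"P{i}" for i in range(scores.shape[0])]),
        snp_ids=np.array(ids or [f"s{j}" for j in range(scores.shape[1])]),
        scores=scores,
    )


def test_build_prs_drops_hla_snps_and_uses_scan_betas():
    df = pd.DataFrame(
        {
            "snp_id": ["hla_snp", "keep1", "keep2"],
            "chrom": ["6", "6", "2"],
            "pos": [26_000_000, 24_000_000, 211_541_165],
            "p": [1e-4, 1e-4, 1e-5],
            "beta": [0.5, 0.913, -0.4],
        }
    )
    scan = _scan_from_frame(df)
    ref = _mismatch(np.random.default_rng(5).integers(0, 3, (40, 3)), ["hla_snp", "keep1", "keep2"])
    model = mp.build_prs_model(list(df["snp_id"]), scan, ref, p_threshold=1e-3)
    assert model.snp_ids == ["keep1", "keep2"]
    np.testing.assert_allclose(model.weights, [0.913, -0.4])
    assert np.exp(model.weights[0]) == pytest.approx(2.49, abs=0.005)


def test_build_prs_empty_after_hla_drop_fails():
    df = pd.DataFrame(
        {"snp_id": ["hla_snp"], "chrom": ["6"], "pos": [30_000_000], "p": [1e-4], "beta": [0.5]}
    )
    ref = _mismatch(np.ones((10, 1)), ["hla_snp"])
    with pytest.raises(ValueError, match="HLA"):
        mp.build_prs_model(["hla_snp"], _scan_from_frame(df), ref, p_threshold=1e-3)


def test_standardized_reference_scores_have_unit_sd():
    rng = np.random.default_rng(6)
    df = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(5)],
            "chrom": ["2"] * 5,
            "pos": np.arange(5) * 10_000 + 1,
            "p": [1e-4] * 5,
            "beta": rng.normal(0.5, 0.2, 5),
        }
    )
    ref = _mismatch(rng.integers(0, 3, (60, 5)))
    model = mp.build_prs_model(list(df["snp_id"]), _scan_from_frame(df), ref, 1e-3)
    z = mp.score_pairs(model, ref)
    assert np.mean(z) == pytest.approx(0.0, abs=1e-12)
    assert np.std(z) == pytest.approx(1.0, abs=1e-12)


def test_score_pairs_arithmetic_and_linearity():
    df = pd.DataFrame(
        {"snp_id": ["s0"], "chrom": ["2"], "pos": [100], "p": [1e-4], "beta": [0.913]}
    )
    ref = _mismatch([[0.0], [1.0], [2.0]])
    model = mp.build_prs_model(["s0"], _scan_from_frame(df), ref, 1e-3)
    raw = model.weights @ np.array([[2.0]])
    assert raw[0] == pytest.approx(1.826)
    # all-zero mismatch gives raw 0 for every pair
    z0 = mp.score_pairs(model, _mismatch([[0.0], [0.0]]))
    assert np.allclose(z0 * model.ref_sd + model.ref_mean * 0, (0 - model.ref_mean) / model.ref_sd * model.ref_sd)
    # doubling weights doubles raw scores
    model2 = mp.build_prs_model(["s0"], _scan_from_frame(df.assign(beta=[1.826])), ref, 1e-3)
    raw1 = mp.score_pairs(model, ref) * model.ref_sd + model.ref_mean
    raw2 = mp.score_pairs(model2, ref) * model2.ref_sd + model2.ref_mean
    np.testing.assert_allclose(raw2, 2 * raw1, atol=1e-12)


def test_score_pairs_invariant_to_snp_order():
    rng = np.random.default_rng(7)
    ids = [f"s{j}" for j in range(6)]
    df = pd.DataFrame(
        {
            "snp_id": ids,
            "chrom": ["3"] * 6,
            "pos": np.arange(6) * 5000 + 1,
            "p": [1e-4] * 6,
            "beta": rng.normal(0, 0.5, 6),
        }
    )
    scores = rng.integers(0, 3, (30, 6)).astype(float)
    ref = _mismatch(scores, ids)
    model = mp.build_prs_model(ids, _scan_from_frame(df), ref, 1e-3)
    perm = [4, 2, 0, 5, 1, 3]
    ref_perm = _mismatch(scores[:, perm], [ids[j] for j in perm])
    np.testing.assert_allclose(mp.score_pairs(model, ref), mp.score_pairs(model, ref_perm), atol=1e-12)


def test_score_pairs_low_coverage_fails():
    rng = np.random.default_rng(8)
    ids = [f"s{j}" for j in range(10)]
    df = pd.DataFrame(
        {
            "snp_id": ids,
            "chrom": ["3"] * 10,
            "pos": np.arange(10) * 5000 + 1,
            "p": [1e-4] * 10,
            "beta": rng.normal(0, 0.5, 10),
        }
    )
    ref = _mismatch(rng.integers(0, 3, (20, 10)), ids)
    model = mp.build_prs_model(ids, _scan_from_frame(df), ref, 1e-3)
    target = _mismatch(rng.integers(0, 3, (20, 8)), ids[:8])  # 80% coverage
    with pytest.raises(ValueError, match="coverage|available"):
        mp.score_pairs(model, target)


def test_model_file_round_trip(tmp_path):
    df = pd.DataFrame(
        {"snp_id": ["s0", "s1"], "chrom": ["2", "3"], "pos": [100, 200], "p": [1e-4, 1e-5], "beta": [0.3, -0.2]}
    )
    ref = _mismatch(np.random.default_rng(9).integers(0, 3, (25, 2)), ["s0", "s1"])
    model = mp.build_prs_model(["s0", "s1"], _scan_from_frame(df), ref, 1e-3)
    model.write(str(tmp_path / "m"))
    import json

    side = json.loads((tmp_path / "m.prs.json").read_text())
    assert side["n_snps"] == 2
    tab = pd.read_csv(tmp_path / "m.prs.tsv", sep="\t")
    np.testing.assert_allclose(tab["weight"], model.weights)


# ---------------------------------------------------------------------------
# Validation and sensitivity
# ---------------------------------------------------------------------------


def test_validate_prs_permutation_null(null_scan_cohort):
    rng = np.random.default_rng(10)
    pvals, hrs = [], []
    prs = rng.normal(size=null_scan_cohort.n_pairs)
    for _ in range(25):
        fit = mp.validate_prs(null_scan_cohort, rng.permutation(prs))
        pvals.append(fit.p[0])
        hrs.append(fit.hr[0])
    assert np.mean(hrs) == pytest.approx(1.0, abs=0.1)
    assert np.mean(np.array(pvals) < 0.05) <= 0.2
    fit = mp.validate_prs(null_scan_cohort, prs)
    ci = fit.conf_int()[0]
    assert ci[0] < fit.hr[0] < ci[1]


def test_sensitivity_refit_no_pairs_removed_equals_original(null_scan_cohort):
    rng = np.random.default_rng(11)
    prs = rng.normal(size=null_scan_cohort.n_pairs)
    phi = np.full(null_scan_cohort.n_pairs, 0.25)  # everyone related
    base = mp.validate_prs(null_scan_cohort, prs)
    refit, report = mp.sensitivity_refit(null_scan_cohort, prs, phi, 0.1)
    np.testing.assert_allclose(refit.coef, base.coef, atol=1e-12)
    assert report["n_removed"] == 0
    assert report["direction"] == "removed_kinship_below_cutoff"


def test_sensitivity_refit_removes_labeled_unrelated_pairs():
    # a dense panel keeps per-pair kinship noise well inside the 0.1 cutoff
    cohort = mp.simulate_cohort(
        mp.SimConfig(n_pairs=60, n_snps=2500, relationship_mix=(0.5, 0.45, 0.05), seed=42)
    )
    phi = mp.cohort_kinship(cohort)
    rng = np.random.default_rng(12)
    prs = rng.normal(size=cohort.n_pairs)
    _, report = mp.sensitivity_refit(cohort, prs, phi, 0.1)
    rel = cohort.phenotype["relationship"].to_numpy()
    removed = set(report["removed_pair_ids"])
    unrelated = set(np.asarray(cohort.pair_ids)[rel == "unrelated"])
    assert removed == unrelated  # kinship threshold isolates the simulated unrelated pairs


def test_sensitivity_refit_both_directions_labeled():
    # balanced mix so both cutoff directions leave enough pairs to refit
    cohort = mp.simulate_cohort(
        mp.SimConfig(n_pairs=80, n_snps=300, relationship_mix=(0.3, 0.3, 0.4), seed=17)
    )
    phi = mp.cohort_kinship(cohort)
    prs = np.random.default_rng(13).normal(size=cohort.n_pairs)
    _, rep_lo = mp.sensitivity_refit(cohort, prs, phi, 0.1, drop_below=True)
    _, rep_hi = mp.sensitivity_refit(cohort, prs, phi, 0.1, drop_below=False)
    assert rep_lo["direction"] != rep_hi["direction"]
    assert rep_lo["n_removed"] + rep_hi["n_removed"] == cohort.n_pairs


def test_sensitivity_refit_too_few_pairs_fails(small_cohort):
    phi = np.zeros(small_cohort.n_pairs)  # everyone below cutoff
    prs = np.random.default_rng(14).normal(size=small_cohort.n_pairs)
    with pytest.raises(ValueError, match="pairs"):
        mp.sensitivity_refit(small_cohort, prs, phi, 0.1)
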