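"""Clumping + thresholding polygenic risk score on mismatch scores.

SNPs are greedily clumped on the training cohort's LD (squared Pearson correlation
of recipient dosages, 200 kb window, r² < 0.2), filtered at a scan P-value cutoff,
stripped of HLA-region SNPs (HLA matching is already a model covariate), and
weighted by the scan's log-hazard estimates.  The resulting score
``raw_i = Σ_j β_j · M_ij`` is standardized per SD and validated in an independent
cohort under the same Cox model as the scan.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .paired_io import COVARIATE_COLUMNS, PairedCohort
from .mismatch_qc import MismatchMatrix, QCThresholds, hla_mask
from .survival_scan import CoxFit, ScanResult, fit_cox, screen_covariates

logger = logging.getLogger(__name__)

DEFAULT_P_CUTOFFS = (5e-2, 1e-2, 1e-3, 1e-4, 1e-5)


@dataclass
class PRSModel:
    """Selected SNPs, their log-hazard weights, and standardization constants."""

    snps: pd.DataFrame  # snp_id, chrom, pos, a0, a1, weight, p_scan
    p_threshold: float
    clump_r2: float = 0.2
    clump_window_kb: float = 200.0
    ref_mean: float = 0.0
    ref_sd: float = 1.0
    reference_cohort: str = "validation"

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps["snp_id"])

    @property
    def weights(self) -> np.ndarray:
        return self.snps["weight"].to_numpy(float)

    def write(self, prefix: str) -> None:
        """Headered TSV of SNPs/weights plus a JSON sidecar of model constants."""
        self.snps.to_csv(f"{prefix}.prs.tsv", sep="\t", index=False)
        sidecar = {
            "p_threshold": self.p_threshold,
            "clump_r2": self.clump_r2,
            "clump_window_kb": self.clump_window_kb,
            "ref_mean": self.ref_mean,
            "ref_sd": self.ref_sd,
            "reference_cohort": self.reference_cohort,
            "n_snps": len(self.snps),
        }
        with open(f"{prefix}.prs.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


def clump(
    scan: ScanResult,
    ld_genotypes: np.ndarray,
    ld_snp_ids: list[str],
    r2_threshold: float = 0.2,
    window_kb: float = 200.0,
) -> list[str]:
    """Greedy LD clumping; returns index-SNP ids in selection order.

    Repeatedly the unassigned SNP with the smallest scan p (ties broken by
    position, then id) becomes an index and removes unassigned SNPs on the same
    chromosome within ``window_kb`` of it whose squared correlation with it (in
    ``ld_genotypes``, samples x SNPs) is at least ``r2_threshold``.  SNPs absent
    from the LD panel count as r² = 0 with a warning.
    """
    tab = scan.table
    tab = tab[np.isfinite(tab["p"])].copy()
    order = tab.sort_values(["p", "pos", "snp_id"], kind="mergesort")
    ld_index = {s: j for j, s in enumerate(ld_snp_ids)}
    missing_ld = [s for s in order["snp_id"] if s not in ld_index]
    if missing_ld:
        logger.warning("clump: %d SNPs absent from LD panel treated as r2=0", len(missing_ld))

    ids = order["snp_id"].to_numpy()
    chroms = order["chrom"].astype(str).to_numpy()
    pos = order["pos"].to_numpy(np.int64)
    assigned = np.zeros(ids.size, dtype=bool)
    indices: list[str] = []
    window_bp = window_kb * 1000.0
    G = np.asarray(ld_genotypes, float)
    for k in range(ids.size):
        if assigned[k]:
            continue
        assigned[k] = True
        indices.append(ids[k])
        near = ~assigned & (chroms == chroms[k]) & (np.abs(pos - pos[k]) <= window_bp)
        cand = np.flatnonzero(near)
        if cand.size == 0 or ids[k] not in ld_index:
            continue
        gk = G[:, ld_index[ids[k]]]
        for c in cand:
            if ids[c] not in ld_index:
                continue
            if squared_correlation(gk, G[:, ld_index[ids[c]]]) >= r2_threshold:
                assigned[c] = True
    return indices


def squared_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pairwise-complete squared Pearson correlation of two dosage vectors."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def threshold_select(
    clumped_ids: list[str],
    scan: ScanResult,
    p_cutoffs: tuple[float, ...] = DEFAULT_P_CUTOFFS,
) -> dict[float, list[str]]:
    """For each cutoff, the clumped SNPs with scan p below it (nested sets)."""
    pvals = scan.pvalues()
    out: dict[float, list[str]] = {}
    for cutoff in sorted(p_cutoffs, reverse=True):
        out[cutoff] = [s for s in clumped_ids if pvals.get(s, np.nan) < cutoff]
    return out


def build_prs_model(
    selected_ids: list[str],
    scan: ScanResult,
    reference_mismatch: MismatchMatrix,
    p_threshold: float,
    thresholds: QCThresholds = QCThresholds(),
    reference_cohort: str = "validation",
    clump_r2: float = 0.2,
    clump_window_kb: float = 200.0,
) -> PRSModel:
    """Weight selected SNPs by scan betas, drop HLA SNPs, fix standardization.

    Standardization constants (mean/SD of the raw score) are computed on
    ``reference_mismatch`` — by default the validation cohort, so the reported
    hazard ratio is per SD of the validation-score distribution.
    """
    tab = scan.table.set_index("snp_id")
    sel = tab.loc[[s for s in selected_ids if s in tab.index]].reset_index()
    hla_ids, _ = hla_mask(
        sel.rename(columns={"a1_freq": "alt_freq"}), thresholds
    )
    if hla_ids:
        logger.info("PRS: dropping %d HLA-region SNPs", len(hla_ids))
        sel = sel[~sel["snp_id"].isin(hla_ids)]
    if sel.empty:
        raise ValueError("no SNPs remain in the PRS model after the HLA-region drop")
    model_snps = sel[["snp_id", "chrom", "pos", "a0", "a1"]].copy()
    model_snps["weight"] = sel["beta"].to_numpy(float)
    model_snps["p_scan"] = sel["p"].to_numpy(float)
    model = PRSModel(
        snps=model_snps.reset_index(drop=True),
        p_threshold=p_threshold,
        clump_r2=clump_r2,
        clump_window_kb=clump_window_kb,
        reference_cohort=reference_cohort,
    )
    raw = _raw_scores(model, reference_mismatch)
    model.ref_mean = float(np.mean(raw))
    sd = float(np.std(raw))
    model.ref_sd = sd if sd > 0 else 1.0
    return model


def _raw_scores(model: PRSModel, mismatch: MismatchMatrix, min_coverage: float = 0.9) -> np.ndarray:
    avail = np.isin(model.snps["snp_id"].to_numpy(), mismatch.snp_ids)
    coverage = avail.mean()
    if coverage < min_coverage:
        n_missing = int((~avail).sum())
        raise ValueError(
            f"only {coverage:.1%} of {len(model.snps)} model SNPs are available in the "
            f"target cohort ({n_missing} missing); need >= {min_coverage:.0%}"
        )
    col = {s: j for j, s in enumerate(mismatch.snp_ids)}
    cols = [col[s] for s in model.snps["snp_id"][avail]]
    W = model.weights[avail]
    M = mismatch.scores[:, cols]
    miss = np.isnan(M)
    if miss.any():
        logger.info(
            "PRS scoring: %d missing pair/SNP mismatch values skipped", int(miss.sum())
        )
    return np.nansum(M * W, axis=1)


def score_pairs(model: PRSModel, mismatch: MismatchMatrix) -> np.ndarray:
    """Standardized PRS per pair: (raw - ref mean) / ref SD.

    Per-pair missing mismatch values are skipped (no score imputation); fails if
    under 90% of model SNPs are present in the target cohort.
    """
    return (_raw_scores(model, mismatch) - model.ref_mean) / model.ref_sd


def validate_prs(cohort: PairedCohort, prs: np.ndarray, tie_method: str = "efron") -> CoxFit:
    """Cox fit of AR time on [PRS, clinical covariates]; HR per SD with 95% CI."""
    pheno = cohort.phenotype
    needed = ["time_days", "event", *COVARIATE_COLUMNS]
    complete = ~pheno[needed].isna().any(axis=1).to_numpy()
    complete &= ~np.isnan(np.asarray(prs, float))
    if not complete.all():
        logger.info("validate_prs: dropped %d incomplete pairs", int((~complete).sum()))
    pheno = pheno.loc[complete]
    time = pheno["time_days"].to_numpy(float)
    event = pheno["event"].to_numpy(int)
    C, covar_names = screen_covariates(
        time, event, pheno[list(COVARIATE_COLUMNS)].to_numpy(float), list(COVARIATE_COLUMNS)
    )
    X = np.column_stack([np.asarray(prs, float)[complete], C])
    return fit_cox(time, event, X, names=["prs", *covar_names], tie_method=tie_method)


def sensitivity_refit(
    cohort: PairedCohort,
    prs: np.ndarray,
    kinship_per_pair: np.ndarray,
    kinship_cutoff: float = 0.1,
    drop_below: bool = True,
    min_pairs: int = 10,
) -> tuple[CoxFit, dict]:
    """Refit the PRS validation after removing pairs on one side of a kinship cutoff.

    ``drop_below=True`` removes pairs with kinship < cutoff (the unrelated pairs, so
    the refit isolates the related majority); ``drop_below=False`` removes the
    related side instead.  Returns the refit plus a labeled report of the direction
    and the removed pairs.
    """
    phi = np.asarray(kinship_per_pair, float)
    removed = (phi < kinship_cutoff) if drop_below else (phi >= kinship_cutoff)
    keep = ~removed
    if keep.sum() < min_pairs:
        raise ValueError(f"only {int(keep.sum())} pairs remain below the {min_pairs}-pair floor")
    sub = cohort.subset_pairs(np.flatnonzero(keep))
    fit = validate_prs(sub, np.asarray(prs, float)[keep])
    report = {
        "direction": "removed_kinship_below_cutoff" if drop_below else "removed_kinship_at_or_above_cutoff",
        "kinship_cutoff": kinship_cutoff,
        "n_removed": int(removed.sum()),
        "n_kept": int(keep.sum()),
        "removed_pair_ids": list(np.asarray(cohort.pair_ids)[removed]),
    }
    return fit, report


def check_clump_independence(
    model_or_ids,
    scan: ScanResult,
    ld_genotypes: np.ndarray,
    ld_snp_ids: list[str],
    r2_threshold: float = 0.2,
    window_kb: float = 200.0,
) -> bool:
    """Post-hoc assertion: no two selected SNPs within the window share r² >= threshold."""
    ids = model_or_ids.snp_ids if isinstance(model_or_ids, PRSModel) else list(model_or_ids)
    tab = scan.table.set_index("snp_id")
    ld_index = {s: j for j, s in enumerate(ld_snp_ids)}
    G = np.asarray(ld_genotypes, float)
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            ra, rb = tab.loc[ids[a]], tab.loc[ids[b]]
            if str(ra["chrom"]) != str(rb["chrom"]):
                continue
            if abs(int(ra["pos"]) - int(rb["pos"])) > window_kb * 1000:
                continue
            if ids[a] in ld_index and ids[b] in ld_index:
                r2 = squared_correlation(G[:, ld_index[ids[a]]], G[:, ld_index[ids[b]]])
                if r2 >= r2_threshold:
                    return False
    return True
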