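"""IBS mismatch scoring, SNP-level QC, HLA masking and donor-recipient kinship.

The identity-by-state (IBS) mismatch score of a donor-recipient pair at one SNP is
the absolute difference of their alt-allele counts, ``M = |D - R|`` in [0, 2].  For
hard calls the score is 0, 1 or 2; in dosage mode it is a fraction.  A SNP whose
mismatch is almost always zero carries no information about between-pair genetic
disparity and is filtered before the survival scan, together with the usual
frequency/missingness/imputation-quality filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .paired_io import PairedCohort

logger = logging.getLogger(__name__)

Mode = Literal["hard_call", "dosage"]


@dataclass
class QCThresholds:
    """SNP-level QC thresholds and the GRCh37 HLA-region bounds (inclusive)."""

    maf_min: float = 0.05
    mean_mismatch_min: float = 0.05
    missing_max: float = 0.10
    info_min: float = 0.80
    hard_call_tolerance: float = 0.10
    hla_chrom: str = "6"
    hla_start: int = 25_759_242
    hla_end: int = 33_534_827

    def __post_init__(self) -> None:
        for name in ("maf_min", "mean_mismatch_min", "missing_max", "info_min", "hard_call_tolerance"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.hla_start >= self.hla_end:
            raise ValueError("hla_start must be < hla_end")

    def metadata(self) -> dict:
        """Interpretation notes recorded alongside QC output."""
        return {
            "maf_min": self.maf_min,
            "mean_mismatch_min": self.mean_mismatch_min,
            "missing_max": self.missing_max,
            "info_min": self.info_min,
            "mismatch_filter_interpretation": (
                "per-SNP mean IBS mismatch across pairs < mean_mismatch_min; "
                "missingness filter applies to the per-SNP sample missing rate"
            ),
        }


@dataclass
class MismatchMatrix:
    """Pairs x SNPs matrix of IBS mismatch scores with per-SNP summaries."""

    pair_ids: np.ndarray
    snp_ids: np.ndarray
    scores: np.ndarray
    mean_mismatch: np.ndarray = field(default=None)  # type: ignore[assignment]
    missing_rate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float)
        vals = self.scores[~np.isnan(self.scores)]
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValueError("mismatch scores outside [0, 2]")
        if self.mean_mismatch is None:
            with np.errstate(invalid="ignore"):
                self.mean_mismatch = np.nanmean(self.scores, axis=0)
        if self.missing_rate is None:
            self.missing_rate = np.isnan(self.scores).mean(axis=0)

    def column(self, snp_id: str) -> np.ndarray:
        j = int(np.flatnonzero(self.snp_ids == snp_id)[0])
        return self.scores[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.pair_ids, columns=self.snp_ids)


def _hard_call(dosage: np.ndarray, tolerance: float) -> np.ndarray:
    """Round dosages within ``tolerance`` of an integer; others become NaN."""
    rounded = np.round(dosage)
    out = np.where(np.abs(dosage - rounded) <= tolerance + 1e-12, rounded, np.nan)
    return np.where(np.isnan(dosage), np.nan, out)


def ibs_mismatch(
    donor,
    recipient,
    mode: Mode = "hard_call",
    hard_call_tolerance: float = 0.1,
):
    """IBS mismatch score ``|D - R|`` for scalar or array dosages.

    In ``hard_call`` mode each dosage is rounded to the nearest integer when within
    ``hard_call_tolerance`` of it and treated as missing otherwise; ``dosage`` mode
    uses the raw values.  Missing in, missing out.
    """
    d = np.asarray(donor, float)
    r = np.asarray(recipient, float)
    for name, x in (("donor", d), ("recipient", r)):
        bad = ~np.isnan(x) & ((x < 0) | (x > 2))
        if bad.any():
            raise ValueError(f"{name} dosage outside [0, 2]")
    if mode == "hard_call":
        d = _hard_call(d, hard_call_tolerance)
        r = _hard_call(r, hard_call_tolerance)
    elif mode != "dosage":
        raise ValueError(f"unknown mode {mode!r}")
    out = np.abs(d - r)
    return out if out.ndim else float(out) if not np.isnan(out) else np.nan


def mismatch_matrix(
    cohort: PairedCohort, mode: Mode = "hard_call", hard_call_tolerance: float = 0.1
) -> MismatchMatrix:
    """Per-pair, per-SNP mismatch scores for a whole cohort."""
    scores = ibs_mismatch(cohort.donor, cohort.recipient, mode, hard_call_tolerance)
    return MismatchMatrix(
        pair_ids=cohort.pair_ids,
        snp_ids=cohort.snps["snp_id"].to_numpy(),
        scores=np.asarray(scores, float),
    )


def expected_mismatch_hwe(q: float) -> float:
    """Expected mean IBS mismatch of an unrelated pair at alt frequency ``q``.

    Enumerating the nine genotype-pair outcomes under Hardy-Weinberg with
    genotype probabilities p0=(1-q)^2, p1=2q(1-q), p2=q^2 gives
    ``2*p0*p1 + 2*p1*p2 + 4*p0*p2`` (the |D-R|=1 transitions each weigh 1, the
    opposite-homozygote outcome weighs 2).
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("allele frequency must be in [0, 1]")
    p0, p1, p2 = (1 - q) ** 2, 2 * q * (1 - q), q**2
    return 2 * p0 * p1 + 2 * p1 * p2 + 4 * p0 * p2


def snp_qc_filter(
    cohort: PairedCohort,
    mismatch: MismatchMatrix,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[list[str], pd.DataFrame]:
    """Apply SNP-level QC; returns retained ids and an exclusion-reason table.

    A SNP is excluded when pooled MAF < ``maf_min``, mean mismatch <
    ``mean_mismatch_min``, missing rate > ``missing_max``, or imputation info <
    ``info_min`` (SNPs without an info value count as genotyped and are never
    filtered on info).  Each excluded SNP carries its first matching reason in the
    fixed order maf, mismatch, missing, info.
    """
    snps = cohort.snps
    pooled = np.concatenate([cohort.donor, cohort.recipient])
    with np.errstate(invalid="ignore"):
        alt_freq = np.nanmean(pooled, axis=0) / 2.0
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    geno_missing = np.isnan(pooled).mean(axis=0)
    missing = np.maximum(geno_missing, mismatch.missing_rate)
    info = snps["imputation_info"].to_numpy(float)

    retained, reasons = [], []
    for j, sid in enumerate(snps["snp_id"]):
        if maf[j] < thresholds.maf_min or np.isnan(maf[j]):
            reasons.append((sid, "maf"))
        elif mismatch.mean_mismatch[j] < thresholds.mean_mismatch_min or np.isnan(
            mismatch.mean_mismatch[j]
        ):
            reasons.append((sid, "mismatch"))
        elif missing[j] > thresholds.missing_max:
            reasons.append((sid, "missing"))
        elif not np.isnan(info[j]) and info[j] < thresholds.info_min:
            reasons.append((sid, "info"))
        else:
            retained.append(sid)
    report = pd.DataFrame(reasons, columns=["snp_id", "reason"])
    report.attrs["thresholds"] = thresholds.metadata()
    logger.info("QC retained %d / %d SNPs", len(retained), len(snps))
    return retained, report


def hla_mask(
    snps: pd.DataFrame, thresholds: QCThresholds = QCThresholds()
) -> tuple[list[str], list[str]]:
    """Split SNP ids into (HLA-region, non-HLA) by inclusive GRCh37 bounds."""
    in_hla = (
        (snps["chrom"].astype(str) == thresholds.hla_chrom)
        & (snps["pos"] >= thresholds.hla_start)
        & (snps["pos"] <= thresholds.hla_end)
    ).to_numpy()
    ids = snps["snp_id"].to_numpy()
    return list(ids[in_hla]), list(ids[~in_hla])


def kinship(
    donor: np.ndarray,
    recipient: np.ndarray,
    hard_call_tolerance: float = 0.1,
    min_snps: int = 1000,
) -> float:
    """Between-pair robust method-of-moments kinship coefficient.

    Uses the opposite-homozygote / shared-heterozygote estimator
    ``phi = (N_het,het - 2 * N_opp_hom) / (N_het(D) + N_het(R))``
    over hard-called SNPs observed in both members.  Needs no allele-frequency
    reference, so it is stable within families.  Expected values: 0.5 for
    self/identical, ~0.25 for parent-offspring and full siblings, ~0 for unrelated.
    """
    d = _hard_call(np.asarray(donor, float).ravel(), hard_call_tolerance)
    r = _hard_call(np.asarray(recipient, float).ravel(), hard_call_tolerance)
    ok = ~np.isnan(d) & ~np.isnan(r)
    d, r = d[ok], r[ok]
    if d.size < min_snps:
        logger.warning("kinship estimated from only %d informative SNPs", d.size)
    het_d = d == 1
    het_r = r == 1
    n_het_het = int(np.sum(het_d & het_r))
    n_opp = int(np.sum(np.abs(d - r) == 2))
    denom = int(het_d.sum() + het_r.sum())
    if denom == 0:
        logger.warning("kinship undefined: no heterozygous genotypes")
        return float("nan")
    return (n_het_het - 2.0 * n_opp) / denom


def cohort_kinship(cohort: PairedCohort, snp_ids: Iterable[str] | None = None) -> np.ndarray:
    """Per-pair kinship estimates over the given (QC-passing) SNPs."""
    if snp_ids is None:
        idx = np.arange(cohort.n_snps)
    else:
        wanted = set(snp_ids)
        idx = np.flatnonzero(cohort.snps["snp_id"].isin(wanted).to_numpy())
    return np.array(
        [kinship(cohort.donor[i, idx], cohort.recipient[i, idx]) for i in range(cohort.n_pairs)]
    )


def write_qc_report(
    mismatch: MismatchMatrix, report: pd.DataFrame, prefix: str
) -> None:
    """Write the mismatch summary and exclusion report as TSV."""
    pd.DataFrame(
        {
            "snp_id": mismatch.snp_ids,
            "mean_mismatch": mismatch.mean_mismatch,
            "missing_rate": mismatch.missing_rate,
        }
    ).to_csv(f"{prefix}.mismatch.tsv", sep="\t", index=False)
    out = report.copy()
    for key, val in report.attrs.get("thresholds", {}).items():
        out.attrs[key] = val
    with open(f"{prefix}.exclusions.tsv", "w") as fh:
        for key, val in report.attrs.get("thresholds", {}).items():
            fh.write(f"# {key}: {val}\n")
        out.to_csv(fh, sep="\t", index=False)
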