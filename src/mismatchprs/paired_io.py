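"""Reading, validating, harmonizing and writing paired donor-recipient cohorts.

A *paired cohort* couples one genotype row per transplant pair member (donor and
recipient) with a time-to-event phenotype table.  Genotypes are stored as alt-allele
dosages in ``[0, 2]``; hard calls are the integer special case.  Missing dosages are
``NaN`` (an out-of-range sentinel, never 0).

Supported on-disk genotype sources:

* PLINK 1 binary filesets (``.bed``/``.bim``/``.fam``, variant-major).  The reader is
  implemented here directly: the format is a three-byte magic followed by one
  2-bit-packed byte block per variant.
* VCF (plain or bgzipped), read through :mod:`cyvcf2`.  When a ``DS`` FORMAT field is
  present it takes precedence over the hard ``GT`` call.

Pairing and phenotype tables are headered CSV/TSV files read with pandas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Phenotype columns required of every cohort, in canonical order.
PHENOTYPE_COLUMNS = (
    "time_days",
    "event",
    "recipient_age",
    "recipient_male",
    "pra_positive",
    "hla_mismatch",
    "prior_nonkidney_tx",
)

#: Clinical covariates entering every Cox model, in canonical order.
COVARIATE_COLUMNS = PHENOTYPE_COLUMNS[2:]

_SNP_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "a0",
    "a1",
    "alt_freq",
    "imputation_info",
    "missing_rate",
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _complement(allele: str) -> str | None:
    """Reverse-complement of a simple allele, or None if any base is unknown."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(allele.upper()))
    except KeyError:
        return None


def is_strand_ambiguous(a0: str, a1: str) -> bool:
    """True for A/T and C/G SNPs, whose strand cannot be resolved from alleles."""
    return _complement(a1) is not None and _complement(a1) == a0.upper()


def make_snp_table(
    snp_id: Sequence[str],
    chrom: Sequence[str],
    pos: Sequence[int],
    a0: Sequence[str],
    a1: Sequence[str],
    alt_freq: Sequence[float] | None = None,
    imputation_info: Sequence[float] | None = None,
    missing_rate: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Assemble and validate a SNP metadata table (one row per variant)."""
    n = len(snp_id)
    tab = pd.DataFrame(
        {
            "snp_id": pd.Series(snp_id, dtype=str),
            "chrom": pd.Series(chrom, dtype=str),
            "pos": pd.Series(pos, dtype=np.int64),
            "a0": pd.Series(a0, dtype=str),
            "a1": pd.Series(a1, dtype=str),
            "alt_freq": np.full(n, np.nan) if alt_freq is None else np.asarray(alt_freq, float),
            "imputation_info": np.full(n, np.nan)
            if imputation_info is None
            else np.asarray(imputation_info, float),
            "missing_rate": np.zeros(n) if missing_rate is None else np.asarray(missing_rate, float),
        }
    )
    _validate_snp_table(tab)
    return tab


def _validate_snp_table(tab: pd.DataFrame) -> None:
    if list(tab.columns) != list(_SNP_COLUMNS):
        raise ValueError(f"SNP table columns must be {_SNP_COLUMNS}, got {tuple(tab.columns)}")
    if tab["snp_id"].duplicated().any():
        dup = tab.loc[tab["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"duplicated SNP id {dup!r}")
    if (tab["pos"] < 1).any():
        raise ValueError("SNP positions must be >= 1 (1-based bp)")
    if (tab["a0"] == tab["a1"]).any() or (tab["a0"] == "").any() or (tab["a1"] == "").any():
        raise ValueError("alleles must be non-empty and distinct")
    for col in ("alt_freq", "imputation_info", "missing_rate"):
        vals = tab[col].to_numpy(float)
        ok = np.isnan(vals) | ((vals >= 0.0) & (vals <= 1.0))
        if not ok.all():
            raise ValueError(f"{col} outside [0, 1]")


@dataclass
class PairedCohort:
    """Aligned donor and recipient dosage matrices plus phenotype for n pairs.

    Row *i* of ``donor`` and ``recipient`` both belong to ``pair_ids[i]``; column *j*
    is described by row *j* of ``snps``.  ``phenotype`` is indexed 0..n-1 in pair
    order and carries :data:`PHENOTYPE_COLUMNS`, possibly plus extra columns (the
    simulator adds the true relationship label and kinship, for example).
    """

    pair_ids: np.ndarray
    donor: np.ndarray
    recipient: np.ndarray
    snps: pd.DataFrame
    phenotype: pd.DataFrame

    def __post_init__(self) -> None:
        self.pair_ids = np.asarray(self.pair_ids, dtype=str)
        self.donor = np.asarray(self.donor, dtype=float)
        self.recipient = np.asarray(self.recipient, dtype=float)
        self.validate()

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def validate(self) -> None:
        if self.donor.shape != self.recipient.shape:
            raise ValueError("donor and recipient matrices differ in shape")
        if self.donor.shape != (len(self.pair_ids), len(self.snps)):
            raise ValueError(
                f"genotype matrices {self.donor.shape} do not match "
                f"{len(self.pair_ids)} pairs x {len(self.snps)} SNPs"
            )
        _validate_snp_table(self.snps)
        for mat, who in ((self.donor, "donor"), (self.recipient, "recipient")):
            vals = mat[~np.isnan(mat)]
            if vals.size and (vals.min() < 0 or vals.max() > 2):
                raise ValueError(f"{who} dosages outside [0, 2]")
        missing = [c for c in PHENOTYPE_COLUMNS if c not in self.phenotype.columns]
        if missing:
            raise ValueError(f"phenotype table lacks columns {missing}")
        if len(self.phenotype) != len(self.pair_ids):
            raise ValueError("phenotype rows do not match pairs")
        ev = self.phenotype["event"].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            raise ValueError("event must be 0/1")
        if (self.phenotype["time_days"].to_numpy(float) <= 0).any():
            raise ValueError("time_days must be > 0")

    def subset_snps(self, index: np.ndarray) -> "PairedCohort":
        """Cohort restricted to SNP columns ``index`` (positional, order kept)."""
        return PairedCohort(
            pair_ids=self.pair_ids,
            donor=self.donor[:, index],
            recipient=self.recipient[:, index],
            snps=self.snps.iloc[index].reset_index(drop=True),
            phenotype=self.phenotype,
        )

    def subset_pairs(self, index: np.ndarray) -> "PairedCohort":
        return PairedCohort(
            pair_ids=self.pair_ids[index],
            donor=self.donor[index],
            recipient=self.recipient[index],
            snps=self.snps,
            phenotype=self.phenotype.iloc[index].reset_index(drop=True),
        )


# ---------------------------------------------------------------------------
# PLINK 1 binary reader
# ---------------------------------------------------------------------------

# 2-bit PLINK .bed codes, variant-major: 00 hom A1, 01 missing, 10 het, 11 hom A2.
# We store the count of the .bim A1 allele (our alt), so 00 -> 2, 10 -> 1, 11 -> 0.
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix: str | Path) -> tuple[list[str], pd.DataFrame, np.ndarray]:
    """Read a PLINK .bed/.bim/.fam fileset.

    Returns ``(sample_ids, snp_table, dosages)`` with dosages of shape
    (samples, snps) holding hard calls 0/1/2 (count of .bim A1) or NaN.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    samples = fam[1].astype(str).tolist()
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    n, m = len(samples), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw.size < 3 or raw[0] != 0x6C or raw[1] != 0x1B:
        raise ValueError(f"{prefix}.bed is not a PLINK binary file")
    if raw[2] != 0x01:
        raise ValueError("only variant-major .bed files are supported")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * m:
        raise ValueError(".bed size inconsistent with .fam/.bim dimensions")
    blocks = body.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.stack(
        [(blocks >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2
    ).reshape(m, bytes_per_snp * 4)[:, :n]
    dosages = _BED_DECODE[codes].T  # samples x snps
    snps = make_snp_table(
        snp_id=bim["snp_id"],
        chrom=bim["chrom"],
        pos=bim["pos"],
        a0=bim["a2"],
        a1=bim["a1"],
        alt_freq=np.nanmean(dosages, axis=0) / 2.0,
        missing_rate=np.isnan(dosages).mean(axis=0),
    )
    return samples, snps, dosages


def read_vcf(path: str | Path) -> tuple[list[str], pd.DataFrame, np.ndarray]:
    """Read genotypes from a VCF; the DS FORMAT field wins over GT when present."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dose_cols = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multi-allelic variant %s", var.ID)
            continue
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, float).reshape(-1)
            col[col < 0] = np.nan  # cyvcf2 missing sentinel
        else:
            gts = np.asarray(var.genotype.array())[:, :2]
            col = np.where((gts < 0).any(axis=1), np.nan, gts.clip(min=0).sum(axis=1)).astype(float)
        rows.append(
            (
                var.ID or f"{var.CHROM}:{var.POS}",
                str(var.CHROM).removeprefix("chr"),
                var.POS,
                var.REF,
                var.ALT[0],
            )
        )
        dose_cols.append(col)
    dosages = np.column_stack(dose_cols) if dose_cols else np.empty((len(samples), 0))
    ids, chroms, poss, a0s, a1s = zip(*rows) if rows else ((),) * 5
    snps = make_snp_table(
        snp_id=list(ids),
        chrom=list(chroms),
        pos=list(poss),
        a0=list(a0s),
        a1=list(a1s),
        alt_freq=np.nanmean(dosages, axis=0) / 2.0 if rows else None,
        missing_rate=np.isnan(dosages).mean(axis=0) if rows else None,
    )
    return samples, snps, dosages


def read_paired_cohort(
    genotype_source: str | Path,
    pairing_table: str | Path,
    phenotype_table: str | Path,
) -> PairedCohort:
    """Assemble a :class:`PairedCohort` from a genotype source plus two tables.

    ``genotype_source`` is either a PLINK prefix (``.bed`` alongside) or a VCF path.
    The pairing table needs columns ``pair_id, donor_id, recipient_id``; the
    phenotype table needs ``pair_id`` plus :data:`PHENOTYPE_COLUMNS`.  Rows come out
    in pairing-table order, SNPs in genotype-source order.
    """
    src = Path(genotype_source)
    if src.suffix in {".vcf", ".gz", ".bcf"} or str(src).endswith(".vcf.gz"):
        samples, snps, dosages = read_vcf(src)
    else:
        samples, snps, dosages = read_plink(src if src.suffix != ".bed" else src.with_suffix(""))
    sample_index = {s: i for i, s in enumerate(samples)}

    pairs = _read_table(pairing_table)
    for col in ("pair_id", "donor_id", "recipient_id"):
        if col not in pairs.columns:
            raise ValueError(f"pairing table lacks column {col!r}")
    pheno = _read_table(phenotype_table).set_index("pair_id")

    donor_rows, recip_rows, pheno_rows = [], [], []
    for rec in pairs.itertuples(index=False):
        for sid in (rec.donor_id, rec.recipient_id):
            if str(sid) not in sample_index:
                raise ValueError(
                    f"pair {rec.pair_id!r}: sample {sid!r} absent from genotype source"
                )
        if rec.pair_id not in pheno.index:
            raise ValueError(f"phenotype row absent for pair {rec.pair_id!r}")
        donor_rows.append(dosages[sample_index[str(rec.donor_id)]])
        recip_rows.append(dosages[sample_index[str(rec.recipient_id)]])
        pheno_rows.append(pheno.loc[rec.pair_id])
    phenotype = pd.DataFrame(pheno_rows).reset_index(drop=True)
    return PairedCohort(
        pair_ids=pairs["pair_id"].astype(str).to_numpy(),
        donor=np.vstack(donor_rows),
        recipient=np.vstack(recip_rows),
        snps=snps,
        phenotype=phenotype,
    )


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------


def harmonize_cohorts(a: PairedCohort, b: PairedCohort) -> tuple[PairedCohort, PairedCohort]:
    """Restrict two cohorts to shared SNPs and orient cohort *b* onto *a*'s alleles.

    For each SNP present in both cohorts (by id):

    * identical ordered allele pairs pass unchanged;
    * swapped alleles (a0/a1 in *b* equal a1/a0 in *a*) recode *b*'s dosage ``g`` to
      ``2 - g`` and its alt_freq to ``1 - alt_freq``;
    * strand flips (and flip+swap) are resolved via reverse complement;
    * strand-ambiguous SNPs (A/T, C/G) are dropped, as are irreconcilable allele
      sets (dropped with a logged count, never an error).
    """
    b_index = {s: j for j, s in enumerate(b.snps["snp_id"])}
    keep_a, keep_b, flip_b = [], [], []
    n_ambiguous = n_irreconcilable = 0
    for i, row in enumerate(a.snps.itertuples(index=False)):
        j = b_index.get(row.snp_id)
        if j is None:
            continue
        if is_strand_ambiguous(row.a0, row.a1):
            n_ambiguous += 1
            continue
        ob = b.snps.iloc[j]
        action = _orientation(row.a0, row.a1, ob["a0"], ob["a1"])
        if action is None:
            n_irreconcilable += 1
            continue
        keep_a.append(i)
        keep_b.append(j)
        flip_b.append(action == "swap")
    if n_ambiguous or n_irreconcilable:
        logger.info(
            "harmonize: dropped %d strand-ambiguous and %d irreconcilable SNPs",
            n_ambiguous,
            n_irreconcilable,
        )
    out_a = a.subset_snps(np.asarray(keep_a, dtype=int))
    out_b = b.subset_snps(np.asarray(keep_b, dtype=int))
    flip = np.asarray(flip_b, dtype=bool)
    if flip.any():
        out_b.donor[:, flip] = 2.0 - out_b.donor[:, flip]
        out_b.recipient[:, flip] = 2.0 - out_b.recipient[:, flip]
        snps = out_b.snps.copy()
        snps.loc[flip, ["a0", "a1"]] = snps.loc[flip, ["a1", "a0"]].to_numpy()
        snps.loc[flip, "alt_freq"] = 1.0 - snps.loc[flip, "alt_freq"]
        out_b = replace(out_b, snps=snps)
    # after orientation, report b on a's (possibly strand-flipped) allele labels
    snps_b = out_b.snps.copy()
    snps_b[["a0", "a1"]] = out_a.snps[["a0", "a1"]].to_numpy()
    out_b = replace(out_b, snps=snps_b)
    return out_a, out_b


def _orientation(a0: str, a1: str, b0: str, b1: str) -> str | None:
    """Classify b's allele pair relative to a's: 'match', 'swap', or None."""
    a0, a1, b0, b1 = a0.upper(), a1.upper(), b0.upper(), b1.upper()
    if (b0, b1) == (a0, a1):
        return "match"
    if (b0, b1) == (a1, a0):
        return "swap"
    c0, c1 = _complement(b0), _complement(b1)
    if c0 is not None and c1 is not None:
        if (c0, c1) == (a0, a1):
            return "match"
        if (c0, c1) == (a1, a0):
            return "swap"
    return None


# ---------------------------------------------------------------------------
# Writers (PLINK text for hard calls, VCF with DS for dosages)
# ---------------------------------------------------------------------------


def write_plink_text(cohort: PairedCohort, prefix: str | Path) -> None:
    """Write donor+recipient hard calls as a PLINK .ped/.map text fileset.

    Samples are emitted as ``<pair>_D`` then ``<pair>_R``.  Dosages are rounded to
    hard calls; use :func:`write_vcf` to preserve fractional dosages.
    """
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for row in cohort.snps.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, pid in enumerate(cohort.pair_ids):
            for tag, mat in (("D", cohort.donor), ("R", cohort.recipient)):
                cols = [f"{pid}_{tag}", f"{pid}_{tag}", "0", "0", "0", "-9"]
                for j, row in enumerate(cohort.snps.itertuples(index=False)):
                    g = mat[i, j]
                    if np.isnan(g):
                        cols += ["0", "0"]
                    else:
                        k = int(round(g))
                        cols += [row.a1] * k + [row.a0] * (2 - k)
                fh.write(" ".join(cols) + "\n")


def write_vcf(cohort: PairedCohort, path: str | Path) -> None:
    """Write the cohort as an uncompressed VCF with GT and 3-decimal DS fields."""
    path = Path(path)
    sample_names = [f"{p}_{t}" for p in cohort.pair_ids for t in ("D", "R")]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt dosage">\n')
        for c in sorted(set(cohort.snps["chrom"]), key=str):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_names) + "\n")
        for j, row in enumerate(cohort.snps.itertuples(index=False)):
            cells = []
            for i in range(cohort.n_pairs):
                for mat in (cohort.donor, cohort.recipient):
                    g = mat[i, j]
                    if np.isnan(g):
                        cells.append("./.:.")
                    else:
                        k = int(round(g))
                        gt = ["0/0", "0/1", "1/1"][min(k, 2)]
                        cells.append(f"{gt}:{g:.3f}")
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.a0}\t{row.a1}\t.\t.\t.\tGT:DS\t"
                + "\t".join(cells)
                + "\n"
            )


def write_pairing_tables(cohort: PairedCohort, prefix: str | Path) -> None:
    """Write ``<prefix>.pairs.csv`` and ``<prefix>.pheno.csv`` companion tables."""
    prefix = Path(prefix)
    pd.DataFrame(
        {
            "pair_id": cohort.pair_ids,
            "donor_id": [f"{p}_D" for p in cohort.pair_ids],
            "recipient_id": [f"{p}_R" for p in cohort.pair_ids],
        }
    ).to_csv(f"{prefix}.pairs.csv", index=False)
    pheno = cohort.phenotype.copy()
    pheno.insert(0, "pair_id", cohort.pair_ids)
    pheno.to_csv(f"{prefix}.pheno.csv", index=False)
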