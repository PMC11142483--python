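"""Gene mapping and gene-set over-representation for PRS SNPs.

PRS SNPs are attributed to every gene whose interval, extended by a maximum
distance (default 20 kb, boundaries inclusive) on both sides, contains the SNP
position; SNPs mapping nowhere are reported.  The mapped (study) genes are then
tested term by term against a user-supplied annotation (GMT gene sets over a
reference gene universe) with a one-sided hypergeometric over-representation test,
fold enrichment, and Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_MAX_DISTANCE_BP = 20_000

GENE_COLUMNS = ("gene_id", "chrom", "start", "end", "strand")


def read_gene_intervals(path: str, fmt: str = "bed") -> pd.DataFrame:
    """Read gene intervals from BED (0-based half-open) or TSV (1-based inclusive).

    Returns a table with 1-based inclusive ``start``/``end`` columns; strand is
    informational only and never affects distances.
    """
    if fmt == "bed":
        raw = pd.read_csv(path, sep="\t", header=None, comment="#")
        genes = pd.DataFrame(
            {
                "gene_id": raw[3] if raw.shape[1] > 3 else raw.index.astype(str),
                "chrom": raw[0].astype(str).str.removeprefix("chr"),
                "start": raw[1].astype(np.int64) + 1,
                "end": raw[2].astype(np.int64),
                "strand": raw[5] if raw.shape[1] > 5 else ".",
            }
        )
    elif fmt == "tsv":
        raw = pd.read_csv(path, sep="\t")
        genes = raw.rename(columns=str.lower)[["gene_id", "chrom", "start", "end"]].copy()
        genes["chrom"] = genes["chrom"].astype(str).str.removeprefix("chr")
        genes["strand"] = raw.get("strand", ".")
    else:
        raise ValueError(f"unknown gene-interval format {fmt!r}")
    if (genes["start"] > genes["end"]).any():
        raise ValueError("gene interval with start > end")
    return genes.reset_index(drop=True)


def read_gmt(path: str) -> dict[str, tuple[str, set[str]]]:
    """Read a GMT file: term_id -> (term_name, gene set)."""
    out: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = (parts[1], {g for g in parts[2:] if g})
    return out


def map_snps_to_genes(
    snp_positions: pd.DataFrame,
    genes: pd.DataFrame,
    max_distance: int = DEFAULT_MAX_DISTANCE_BP,
) -> dict[str, set[str]]:
    """Map each SNP to all genes within ``max_distance`` bp (inclusive boundary).

    ``snp_positions`` needs columns snp_id/chrom/pos; ``genes`` needs
    :data:`GENE_COLUMNS` (1-based inclusive).  Distance is measured from the SNP
    position to the nearest interval edge; SNPs inside a gene are at distance 0.
    SNPs with no gene map to the empty set (their count is logged).
    """
    mapping: dict[str, set[str]] = {}
    by_chrom = {str(c): g for c, g in genes.groupby(genes["chrom"].astype(str))}
    n_unmapped = 0
    for row in snp_positions.itertuples(index=False):
        chrom_genes = by_chrom.get(str(row.chrom))
        hits: set[str] = set()
        if chrom_genes is not None:
            lo = chrom_genes["start"].to_numpy(np.int64) - max_distance
            hi = chrom_genes["end"].to_numpy(np.int64) + max_distance
            inside = (row.pos >= lo) & (row.pos <= hi)
            hits = set(chrom_genes["gene_id"].to_numpy()[inside])
        mapping[row.snp_id] = hits
        n_unmapped += not hits
    if n_unmapped:
        logger.info(
            "map_snps_to_genes: %d / %d SNPs map to no gene within %d bp",
            n_unmapped,
            len(snp_positions),
            max_distance,
        )
    return mapping


def overrepresentation_test(
    study_genes: set[str],
    annotation: dict[str, tuple[str, set[str]]],
    reference_genes: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of study genes per term.

    Per term: P(X >= k) with population ``n_ref``, successes ``n_ref_in_term``,
    draws ``n_study``; fold enrichment (k/n_study)/(n_ref_in_term/n_ref);
    Benjamini-Hochberg FDR across all tested terms.  Rows sorted by raw p.
    """
    study = set(study_genes)
    ref = set(reference_genes)
    if not study:
        raise ValueError("empty study gene set")
    if not study <= ref:
        extra = sorted(study - ref)[:5]
        raise ValueError(f"study genes missing from the reference universe, e.g. {extra}")
    n_study, n_ref = len(study), len(ref)
    rows = []
    for term_id, (term_name, genes) in annotation.items():
        term_genes = genes & ref
        k = len(study & term_genes)
        K = len(term_genes)
        if K == 0:
            continue
        p = float(hypergeom.sf(k - 1, n_ref, K, n_study))
        fold = (k / n_study) / (K / n_ref)
        rows.append((term_id, term_name, k, n_study, K, n_ref, fold, p))
    out = pd.DataFrame(
        rows,
        columns=[
            "term_id",
            "term_name",
            "n_study_in_term",
            "n_study",
            "n_ref_in_term",
            "n_ref",
            "fold_enrichment",
            "p_value",
        ],
    )
    if out.empty:
        return out.assign(fdr_adjusted_p=[])
    out["fdr_adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)


@dataclass
class EnrichmentResult:
    """Mapped genes plus the over-representation table."""

    snp_to_genes: dict[str, set[str]]
    table: pd.DataFrame

    @property
    def study_genes(self) -> set[str]:
        return set().union(*self.snp_to_genes.values()) if self.snp_to_genes else set()

    @property
    def fraction_unmapped(self) -> float:
        if not self.snp_to_genes:
            return float("nan")
        return float(np.mean([not g for g in self.snp_to_genes.values()]))

    def write(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def enrich_prs_snps(
    snp_positions: pd.DataFrame,
    genes: pd.DataFrame,
    annotation: dict[str, tuple[str, set[str]]],
    max_distance: int = DEFAULT_MAX_DISTANCE_BP,
    reference_genes: set[str] | None = None,
) -> EnrichmentResult:
    """Map PRS SNPs to genes (unique genes counted once) and test all terms.

    The reference universe defaults to every gene in the interval table.
    """
    mapping = map_snps_to_genes(snp_positions, genes, max_distance)
    study = set().union(*mapping.values()) if mapping else set()
    ref = set(genes["gene_id"]) if reference_genes is None else set(reference_genes)
    table = overrepresentation_test(study, annotation, ref)
    return EnrichmentResult(snp_to_genes=mapping, table=table)
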