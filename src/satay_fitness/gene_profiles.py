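"""Positional read-count diagnostics along coding regions.

Two diagnostics expose where insertions land within genes and with how
many reads, before any of the fitness pipeline's filtering:

* a 20-bin profile of reads per insertion along the coding strand — for
  essential genes this is U-shaped (tolerated insertions cluster near the
  start and especially the stop codon, which only truncates the protein);
* the largest insertion-free span of a gene as a fraction of its length —
  long spans are the classic essentiality signal.

Edge insertions are deliberately included here: the diagnostic must show
the edge effect that the fitness pipeline excludes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .fitness_core import relative_position
from .genome_io import GeneAnnotation, InsertionMap

N_BINS = 20


@dataclass
class BinProfile:
    """Pooled per-bin insertion and read totals over a gene class.

    ``mean_reads[k]`` is (reads in bin k) / (insertions in bin k), the
    average read count per insertion site; NaN for bins with no
    insertions (undefined, not zero).
    """

    insertions: np.ndarray   # int, length 20
    reads: np.ndarray        # int, length 20
    mean_reads: np.ndarray   # float, NaN where undefined
    scope: str
    n_genes: int

    @property
    def n_bins(self) -> int:
        return len(self.insertions)


@dataclass(frozen=True)
class SpanStat:
    """Largest insertion-free span of a gene, as a fraction of its length."""

    gene_id: str
    span_fraction: float


def _select(genes: Iterable[GeneAnnotation], class_filter: str) -> list[GeneAnnotation]:
    if class_filter == "all":
        return list(genes)
    if class_filter == "essential":
        return [g for g in genes if g.essential]
    if class_filter == "nonessential":
        return [g for g in genes if not g.essential]
    raise ValueError(f"unknown class filter {class_filter!r}")


def bin_profile(
    imap: InsertionMap,
    genes: Sequence[GeneAnnotation],
    class_filter: str = "all",
    n_bins: int = N_BINS,
    per_gene_mean: bool = False,
) -> BinProfile:
    """Read-count profile over ``n_bins`` equal segments of the coding region.

    Bin k covers coding-strand relative positions [k/n, (k+1)/n), last bin
    closed. By default bins pool insertions across the gene class (the
    per-bin mean weights every insertion equally); ``per_gene_mean=True``
    instead averages each gene's own per-bin mean across genes.
    """
    selected = _select(genes, class_filter)
    insertions = np.zeros(n_bins, dtype=np.int64)
    reads_total = np.zeros(n_bins, dtype=np.int64)
    per_gene_sums = np.zeros(n_bins)
    per_gene_counts = np.zeros(n_bins, dtype=np.int64)
    for gene in selected:
        pos, reads = imap.sites_in(gene.chrom, gene.start, gene.end)
        if len(pos) == 0:
            continue
        rel = relative_position(gene, pos)
        bins = np.minimum((rel * n_bins).astype(int), n_bins - 1)
        counts = np.bincount(bins, minlength=n_bins)
        sums = np.bincount(bins, weights=reads, minlength=n_bins)
        insertions += counts
        reads_total += sums.astype(np.int64)
        occupied = counts > 0
        with np.errstate(invalid="ignore"):
            gene_mean = np.where(occupied, sums / np.maximum(counts, 1), 0.0)
        per_gene_sums[occupied] += gene_mean[occupied]
        per_gene_counts += occupied
    if per_gene_mean:
        with np.errstate(invalid="ignore"):
            mean = np.where(per_gene_counts > 0, per_gene_sums / per_gene_counts, np.nan)
    else:
        with np.errstate(invalid="ignore"):
            mean = np.where(insertions > 0, reads_total / insertions, np.nan)
    return BinProfile(
        insertions=insertions,
        reads=reads_total,
        mean_reads=mean,
        scope=class_filter,
        n_genes=len(selected),
    )


def insertion_free_span(imap: InsertionMap, gene: GeneAnnotation) -> SpanStat:
    """Largest gap free of insertions within a gene, as a fraction of L_g.

    Gaps are measured between consecutive observed insertion positions,
    with the gene boundaries as sentinels (boundary-to-first insertion and
    last insertion-to-boundary count). A gene without insertions has span
    fraction 1 — its whole coding region is insertion-free.
    """
    pos, _ = imap.sites_in(gene.chrom, gene.start, gene.end)
    if len(pos) == 0:
        return SpanStat(gene.gene_id, 1.0)
    edges = np.concatenate([[gene.start], pos, [gene.end]])
    span = int(np.max(np.diff(edges)))
    return SpanStat(gene.gene_id, span / gene.length)
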