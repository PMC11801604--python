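"""Agreement between two insertion datasets: matched sites and read deltas.

Two replicate libraries are compared site-by-site: insertions within a
2-bp window of each other are matched one-to-one (read mapping is only
accurate to a couple of base pairs) and their read-count difference
delta_R recorded; an insertion with no partner within the window counts
toward the differential-presence tally delta_P, but only if it carries at
least two reads (a single read in one library is not treated as evidence
that the site is differentially present).

Read counts are depth-normalised before the headline delta_R (reads per
total mapped reads of each library); raw deltas are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import InsertionMap


@dataclass
class MatchResult:
    """Site matching between two insertion maps."""

    pairs: pd.DataFrame          # chrom, pos_a, reads_a, pos_b, reads_b, delta_r_raw, delta_r
    delta_p: int                 # differentially-present sites (reads >= min_reads)
    n_unmatched_a: int
    n_unmatched_b: int
    window: int
    totals: tuple[int, int] = (0, 0)

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    @property
    def mean_delta_r(self) -> float:
        """Mean absolute depth-normalised read difference over matched pairs."""
        if len(self.pairs) == 0:
            return 0.0
        return float(self.pairs["delta_r"].mean())

    @property
    def mean_delta_r_raw(self) -> float:
        if len(self.pairs) == 0:
            return 0.0
        return float(self.pairs["delta_r_raw"].mean())


def _match_chrom(
    pos_a: np.ndarray, pos_b: np.ndarray, window: int
) -> list[tuple[int, int]]:
    """One-to-one greedy matching of sorted position arrays.

    Candidate pairs within the window are taken in a symmetric order —
    lower coordinate first, then smaller distance, then the lower partner
    coordinate — so the matching is invariant under swapping A and B.
    """
    candidates: list[tuple[int, int, int, int, int]] = []
    j0 = 0
    for i, p in enumerate(pos_a.tolist()):
        j0 = int(np.searchsorted(pos_b, p - window, side="left"))
        j = j0
        while j < len(pos_b) and pos_b[j] <= p + window:
            q = int(pos_b[j])
            candidates.append((min(p, q), abs(p - q), max(p, q), i, j))
            j += 1
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return pairs


def match_insertions(
    a: InsertionMap,
    b: InsertionMap,
    window: int = 2,
    min_reads_unmatched: int = 2,
) -> MatchResult:
    """Match insertion sites of two libraries within ``window`` bp.

    Matching is one-to-one per chromosome. Unmatched sites with at least
    ``min_reads_unmatched`` reads count toward delta_P; self-comparison
    yields delta_P = 0 and all read deltas 0.
    """
    total_a = max(a.total_reads, 1)
    total_b = max(b.total_reads, 1)
    rows = []
    delta_p = 0
    unmatched_a = unmatched_b = 0
    for chrom in sorted(set(a.chromosomes) | set(b.chromosomes)):
        pos_a, reads_a = a.sites.get(chrom, (np.array([], dtype=np.int64),) * 2)
        pos_b, reads_b = b.sites.get(chrom, (np.array([], dtype=np.int64),) * 2)
        pairs = _match_chrom(pos_a, pos_b, window)
        idx_a = {i for i, _ in pairs}
        idx_b = {j for _, j in pairs}
        for i, j in pairs:
            ra, rb = int(reads_a[i]), int(reads_b[j])
            rows.append(
                {
                    "chrom": chrom,
                    "pos_a": int(pos_a[i]),
                    "reads_a": ra,
                    "pos_b": int(pos_b[j]),
                    "reads_b": rb,
                    "delta_r_raw": abs(ra - rb),
                    "delta_r": abs(ra / total_a - rb / total_b),
                }
            )
        for i in range(len(pos_a)):
            if i not in idx_a:
                unmatched_a += 1
                if reads_a[i] >= min_reads_unmatched:
                    delta_p += 1
        for j in range(len(pos_b)):
            if j not in idx_b:
                unmatched_b += 1
                if reads_b[j] >= min_reads_unmatched:
                    delta_p += 1
    pairs_df = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos_a",
            "reads_a",
            "pos_b",
            "reads_b",
            "delta_r_raw",
            "delta_r",
        ],
    )
    return MatchResult(
        pairs=pairs_df,
        delta_p=delta_p,
        n_unmatched_a=unmatched_a,
        n_unmatched_b=unmatched_b,
        window=window,
        totals=(a.total_reads, b.total_reads),
    )


@dataclass
class FitnessComparison:
    """Paired per-gene fitness between two datasets."""

    table: pd.DataFrame          # gene_id, w_a, w_b, deviation
    pearson: float
    spearman: float
    scale: str
    excluded: int = 0

    @property
    def mean_deviation(self) -> float:
        return float(self.table["deviation"].mean()) if len(self.table) else 0.0


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for r in records:
        rows.append(
            {
                "gene_id": r.gene_id,
                "status": r.status,
                "expected_insertions": r.expected_insertions,
                "fitness_median_scale": r.fitness_median_scale,
                "fitness_generation_scale": r.fitness_generation_scale,
            }
        )
    return pd.DataFrame(rows)


def compare_fitness_tables(
    records_a,
    records_b,
    scale: str = "median",
    min_expected: int = 5,
) -> FitnessComparison:
    """Pair per-gene fitness values of two datasets and correlate them.

    Genes enter when determined (status ``ok``) in both datasets and their
    expected insertion count is at least ``min_expected`` in both (too few
    expected insertions means too little information for a reliable
    estimate). Deviation is w_a - w_b, for interaction-style screening of
    genes off the identity line.
    """
    col = {
        "median": "fitness_median_scale",
        "generation": "fitness_generation_scale",
    }[scale]
    fa = _records_frame(records_a)
    fb = _records_frame(records_b)
    merged = fa.merge(fb, on="gene_id", suffixes=("_a", "_b"))
    keep = (
        (merged["status_a"] == "ok")
        & (merged["status_b"] == "ok")
        & (merged["expected_insertions_a"] >= min_expected)
        & (merged["expected_insertions_b"] >= min_expected)
    )
    excluded = int((~keep).sum())
    merged = merged[keep]
    if len(merged) < 3:
        raise ValueError(
            f"only {len(merged)} genes shared between the datasets (need >= 3)"
        )
    w_a = merged[f"{col}_a"].to_numpy(dtype=float)
    w_b = merged[f"{col}_b"].to_numpy(dtype=float)
    table = pd.DataFrame(
        {
            "gene_id": merged["gene_id"].to_numpy(),
            "w_a": w_a,
            "w_b": w_b,
            "deviation": w_a - w_b,
        }
    )
    if np.std(w_a) == 0 or np.std(w_b) == 0:
        pearson = 1.0 if np.allclose(w_a - w_a.mean(), w_b - w_b.mean()) else float("nan")
        spearman = pearson
    else:
        pearson = float(stats.pearsonr(w_a, w_b).statistic)
        spearman = float(stats.spearmanr(w_a, w_b).statistic)
    return FitnessComparison(
        table=table, pearson=pearson, spearman=spearman, scale=scale, excluded=excluded
    )
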