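"""Sequencing-depth subsampling and saturation analysis.

A sequencing run of depth n is emulated by drawing n reads without
replacement from the pooled reads of a full-depth insertion map — a
multivariate hypergeometric draw with one urn colour per insertion site.
Rerunning the fitness pipeline on each subsample shows how the number of
observed insertion sites, the reads per site, and the relative standard
error of the fitness estimates respond to depth. In real SATAY libraries
most sites carry a single read even at ~1e8 reads, so extra depth mainly
rediscovers the same sites; these curves make that visible for any map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .genome_io import CentromereMap, GeneAnnotation, InsertionMap


@dataclass
class SaturationPoint:
    """Summary of one subsampled depth."""

    n_sampled: int
    unique_insertions: int
    mean_reads_per_site: float
    median_reads_per_site: float
    rel_se_median: float = float("nan")
    rel_se_q25: float = float("nan")
    rel_se_q75: float = float("nan")
    n_ok_genes: int = 0


def subsample_reads(
    imap: InsertionMap, n: int, seed: int | np.random.Generator = 0
) -> InsertionMap:
    """Draw ``n`` reads without replacement from the pooled map.

    Exact multivariate hypergeometric sampling over all sites of all
    chromosomes; sites drawn zero times are dropped. ``n`` equal to the
    total read count returns the input map unchanged (exhaustive draw).
    """
    total = imap.total_reads
    if n < 0 or n > total:
        raise ValueError(f"cannot sample {n} reads from a map with {total}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = imap.chromosomes
    counts = np.concatenate([imap.reads(c) for c in chroms]) if chroms else np.array([], dtype=np.int64)
    if len(counts) == 0 or n == 0:
        return InsertionMap(sites={}, sample_name=f"{imap.sample_name}@n={n}")
    sampled = rng.multivariate_hypergeometric(counts, n, method="marginals")
    sites: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    offset = 0
    for chrom in chroms:
        pos = imap.positions(chrom)
        sub = sampled[offset : offset + len(pos)]
        offset += len(pos)
        keep = sub > 0
        if keep.any():
            sites[chrom] = (pos[keep].copy(), sub[keep].astype(np.int64))
    return InsertionMap(sites=sites, sample_name=f"{imap.sample_name}@n={n}")


def default_depths(total_reads: int, n_points: int = 10) -> list[int]:
    """Log-spaced depth grid from 1% to 100% of the total read count."""
    if total_reads < 1:
        return []
    depths = np.unique(
        np.round(np.geomspace(max(1, total_reads // 100), total_reads, n_points))
    ).astype(int)
    return depths.tolist()


def saturation_curve(
    imap: InsertionMap,
    genes: list[GeneAnnotation] | None = None,
    cen: CentromereMap | None = None,
    depths: list[int] | None = None,
    seed: int = 0,
    config: RunConfig | None = None,
) -> list[SaturationPoint]:
    """Subsample at each depth and summarise library and fitness statistics.

    When ``genes`` and ``cen`` are given the full fitness pipeline is rerun
    per depth and the distribution of the relative standard error
    SE_g / y_hat_g across determined genes is summarised; otherwise only
    the library-level statistics are reported.
    """
    from . import fitness_core  # deferred: avoids an import cycle

    cfg = config or RunConfig()
    if depths is None:
        depths = default_depths(imap.total_reads)
    rng = np.random.default_rng(seed)
    points: list[SaturationPoint] = []
    for n in depths:
        sub = subsample_reads(imap, int(n), rng)
        if sub.total_insertions:
            reads = np.concatenate([sub.reads(c) for c in sub.chromosomes])
            mean_r = float(reads.mean())
            median_r = float(np.median(reads))
        else:
            mean_r = median_r = float("nan")
        point = SaturationPoint(
            n_sampled=int(n),
            unique_insertions=sub.total_insertions,
            mean_reads_per_site=mean_r,
            median_reads_per_site=median_r,
        )
        if genes is not None and cen is not None:
            try:
                result = fitness_core.estimate_fitness(sub, genes, cen, config=cfg)
            except ValueError:
                result = None
            if result is not None:
                rel_se = np.array(
                    [
                        r.standard_error / r.mean_reads
                        for r in result.records
                        if r.status == "ok" and r.mean_reads > 0
                    ]
                )
                if len(rel_se):
                    q25, q50, q75 = np.percentile(rel_se, [25, 50, 75])
                    point.rel_se_median = float(q50)
                    point.rel_se_q25 = float(q25)
                    point.rel_se_q75 = float(q75)
                    point.n_ok_genes = len(rel_se)
        points.append(point)
    return points


def curve_frame(points: list[SaturationPoint]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in points])
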