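"""Forward simulator for SATAY libraries with known ground truth.

The simulator reproduces, stage by stage, the generative process the
estimators assume, so every estimator has a recovery test against a known
truth:

1. **Insertion placement.** Every base pair receives an insertion
   independently, with probability elevated near the centromere: the
   per-bp rate decays linearly from ``rate_near`` (default 0.12 bp^-1) at
   the centromere to ``rate_plateau`` (default 0.067 bp^-1) at
   ``decay_length`` (default 200 kb) and is constant beyond — the range
   SATAY libraries show.
2. **Clonal expansion.** Each insertion mutant starts from one cell and
   grows to 2^(mu*t) cells over ``t`` (default 10) generations. ``mu`` is
   the gene's growth rate for insertions in the central 80% of a gene, 1
   (wild-type-like) outside genes; essential genes have mu = 0 centrally
   with a linear ramp to 1 across the outer 10% (edge insertions often
   fail to knock the gene out).
3. **Harvest bottleneck.** A multinomial sample of ``bottleneck_per_site``
   cells per site on average, taken from the grown population — the
   sampling step at which slow growers are lost.
4. **PCR + sequencing.** Read counts are gamma-Poisson (negative
   binomial) around means proportional to sampled abundance: a per-site
   gamma factor with dispersion ``alpha`` absorbs PCR amplification noise,
   and a Poisson draw models read sampling. Sites with zero reads are
   absent from the output map, exactly as in real data.

``simulate_replicate_pair`` re-randomises only the stages downstream of a
chosen split point, mirroring replicate designs that split the experiment
before expansion, before PCR, or before sequencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import CentromereMap, GeneAnnotation, InsertionMap

SPLIT_POINTS = ("expansion", "pcr", "sequencing", "none")


@dataclass
class SyntheticGenome:
    """Simulated chromosomes: gene annotation, centromeres, lengths."""

    genes: list[GeneAnnotation]
    centromeres: CentromereMap
    chrom_lengths: dict[str, int]


@dataclass
class SyntheticTruth:
    """Ground-truth parameters behind one simulated library."""

    growth_rate: dict[str, float]        # per-gene mu, doublings per generation
    alpha: float                         # NB overdispersion of read counts
    rate_near: float = 0.12              # insertion rate at the centromere, bp^-1
    rate_plateau: float = 0.067          # insertion rate far from it, bp^-1
    decay_length: int = 200_000          # bp over which the elevation decays
    t: float = 10.0                      # generations of library expansion
    bottleneck_per_site: float = 20.0    # mean cells sampled per insertion site
    edge_fraction: float = 0.10          # width of the essential-gene mu ramp
    seed: int = 0

    def true_fitness(self) -> dict[str, float]:
        """mu_g scaled to the median gene — the w the pipeline estimates."""
        mus = np.array(list(self.growth_rate.values()))
        med = float(np.median(mus))
        if med == 0:
            raise ValueError("median true growth rate is 0; fitness scale undefined")
        return {g: mu / med for g, mu in self.growth_rate.items()}

    def insertion_rate(self, r_c) -> np.ndarray:
        """True per-bp insertion probability at centromere distance r_c.

        The elevation decays quadratically from ``rate_near`` at the
        centromere to ``rate_plateau`` at ``decay_length``, approaching the
        plateau with zero slope (the rate levels off smoothly rather than
        kinking). The implied cumulative insertion curve is piecewise
        cubic — the functional family the bias-correction fit assumes.
        """
        r = np.asarray(r_c, dtype=float)
        frac = np.clip(1.0 - r / self.decay_length, 0.0, None) ** 2
        return self.rate_plateau + (self.rate_near - self.rate_plateau) * frac


def simulate_genome(
    n_chrom: int = 2,
    arm_length: int | tuple[int, int] = 300_000,
    n_genes: int = 200,
    essential_fraction: float = 0.15,
    seed: int = 0,
    gene_length_range: tuple[int, int] = (300, 4000),
    centromere_length: int = 120,
    min_gap: int = 100,
    max_gap: int = 2_000,
) -> SyntheticGenome:
    """Build a compact genome of non-overlapping genes around centromeres.

    ``arm_length`` is either one length for both arms or a (left, right)
    pair applied to every chromosome. Genes are packed with random
    intergenic gaps, never overlapping the centromere; exactly
    ``round(essential_fraction * n_genes)`` genes are flagged essential.
    """
    rng = np.random.default_rng(seed)
    if isinstance(arm_length, int):
        left_arm = right_arm = arm_length
    else:
        left_arm, right_arm = arm_length
    centromeres: CentromereMap = {}
    chrom_lengths: dict[str, int] = {}
    free: list[tuple[str, int, int]] = []  # chrom, start, end of gene-placeable spans
    for k in range(n_chrom):
        chrom = f"chr{k + 1}"
        cen_start = left_arm + 1
        cen_end = left_arm + centromere_length
        length = left_arm + centromere_length + right_arm
        centromeres[chrom] = (cen_start, cen_end)
        chrom_lengths[chrom] = length
        free.append((chrom, 1, left_arm))
        free.append((chrom, cen_end + 1, length))

    genes: list[GeneAnnotation] = []
    span_idx = 0
    cursors = {i: span[1] for i, span in enumerate(free)}
    lo_len, hi_len = gene_length_range
    while len(genes) < n_genes:
        placed = False
        for _ in range(len(free)):
            i = span_idx % len(free)
            span_idx += 1
            chrom, _, span_end = free[i]
            gap = int(rng.integers(min_gap, max_gap + 1))
            length = int(rng.integers(lo_len, hi_len + 1))
            start = cursors[i] + gap
            end = start + length - 1
            if end <= span_end:
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(
                    GeneAnnotation(
                        gene_id=f"G{len(genes) + 1:04d}",
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                    )
                )
                cursors[i] = end
                placed = True
                break
        if not placed:
            raise ValueError(
                f"cannot place {n_genes} genes on the requested arms "
                f"(placed {len(genes)})"
            )
    n_essential = round(essential_fraction * n_genes)
    essential_idx = rng.choice(len(genes), size=n_essential, replace=False)
    essential_set = set(essential_idx.tolist())
    genes = [
        GeneAnnotation(
            g.gene_id, g.chrom, g.start, g.end, g.strand, essential=i in essential_set
        )
        for i, g in enumerate(genes)
    ]
    return SyntheticGenome(genes=genes, centromeres=centromeres, chrom_lengths=chrom_lengths)


def default_truth(
    genome: SyntheticGenome,
    seed: int = 0,
    alpha: float = 0.1,
    neutral_sd: float = 0.05,
    deleterious_fraction: float = 0.2,
    deleterious_range: tuple[float, float] = (0.1, 0.9),
    **kwargs,
) -> SyntheticTruth:
    """Draw a ground-truth growth-rate map with a realistic fitness spectrum.

    Most disruptions are near-neutral (mu ~ Normal(1, neutral_sd), clipped
    at 0), a ``deleterious_fraction`` draws uniformly from
    ``deleterious_range``, and essential genes get mu = 0 — together a
    unimodal distribution with a tail toward low fitness.
    """
    rng = np.random.default_rng(seed)
    growth: dict[str, float] = {}
    for gene in genome.genes:
        if gene.essential:
            growth[gene.gene_id] = 0.0
        elif rng.random() < deleterious_fraction:
            growth[gene.gene_id] = float(rng.uniform(*deleterious_range))
        else:
            growth[gene.gene_id] = float(max(0.0, rng.normal(1.0, neutral_sd)))
    return SyntheticTruth(growth_rate=growth, alpha=alpha, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# simulation stages


def _centromere_distances(
    positions: np.ndarray, cen: tuple[int, int]
) -> np.ndarray:
    cen_start, cen_end = cen
    d = np.where(
        positions < cen_start,
        cen_start - positions,
        np.where(positions > cen_end, positions - cen_end, 0),
    )
    return d


def place_insertions(
    genome: SyntheticGenome, truth: SyntheticTruth, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bp Bernoulli insertion placement with the centromere-biased rate.

    Returns (chrom index array, position array, per-site growth rate).
    """
    chrom_idx_list, pos_list = [], []
    chroms = sorted(genome.chrom_lengths)
    for ci, chrom in enumerate(chroms):
        length = genome.chrom_lengths[chrom]
        positions = np.arange(1, length + 1)
        r_c = _centromere_distances(positions, genome.centromeres[chrom])
        p = truth.insertion_rate(r_c)
        hit = rng.random(length) < p
        pos = positions[hit]
        pos_list.append(pos)
        chrom_idx_list.append(np.full(len(pos), ci, dtype=np.int32))
    chrom_idx = np.concatenate(chrom_idx_list)
    pos = np.concatenate(pos_list)
    mu = _site_growth_rates(genome, truth, chrom_idx, pos, chroms)
    return chrom_idx, pos, mu


def _site_growth_rates(
    genome: SyntheticGenome,
    truth: SyntheticTruth,
    chrom_idx: np.ndarray,
    pos: np.ndarray,
    chroms: list[str],
) -> np.ndarray:
    """Growth rate of the mutant at each insertion site.

    Intergenic insertions are wild-type-like (mu = 1). Within a gene the
    rate is the gene's mu; essential genes ramp linearly from mu = 0 at the
    central-region boundary to 1 at the gene edge, emulating the tolerance
    of gene ends to insertions.
    """
    mu = np.ones(len(pos))
    by_chrom: dict[str, list[GeneAnnotation]] = {c: [] for c in chroms}
    for gene in genome.genes:
        by_chrom[gene.chrom].append(gene)
    for ci, chrom in enumerate(chroms):
        sel = chrom_idx == ci
        p = pos[sel]
        genes = sorted(by_chrom[chrom], key=lambda g: g.start)
        if not genes:
            continue
        starts = np.array([g.start for g in genes])
        ends = np.array([g.end for g in genes])
        gi = np.searchsorted(starts, p, side="right") - 1
        inside = (gi >= 0) & (p <= ends[np.clip(gi, 0, None)])
        mu_sel = np.ones(len(p))
        edge = truth.edge_fraction
        for k in np.nonzero(inside)[0]:
            gene = genes[gi[k]]
            g_mu = truth.growth_rate[gene.gene_id]
            if not gene.essential:
                mu_sel[k] = g_mu
                continue
            rel = (p[k] - gene.start) / gene.length
            if gene.strand == "-":
                rel = (gene.end - p[k]) / gene.length
            dist_to_edge = min(rel, 1.0 - rel)
            if dist_to_edge >= edge:
                mu_sel[k] = g_mu
            else:
                # linear ramp: wild-type at the very edge, g_mu at the boundary
                frac = dist_to_edge / edge
                mu_sel[k] = 1.0 + (g_mu - 1.0) * frac
        mu[sel] = mu_sel
    return mu


def grow_and_bottleneck(
    mu: np.ndarray,
    t: float,
    bottleneck_per_site: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Malthusian growth N = 2^(mu*t), then a multinomial harvest sample."""
    n_cells = np.exp2(mu * t)
    total = n_cells.sum()
    if total <= 0:
        return np.zeros(len(mu), dtype=np.int64)
    bottleneck = int(round(bottleneck_per_site * len(mu)))
    return rng.multinomial(bottleneck, n_cells / total).astype(np.int64)


def pcr_factors(alpha: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Per-site gamma amplification factors, mean 1, variance alpha."""
    if alpha <= 0:
        return np.ones(size)
    return rng.gamma(shape=1.0 / alpha, scale=alpha, size=size)


def sequence_reads(
    abundance: np.ndarray,
    factors: np.ndarray,
    depth: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson read sampling around means proportional to abundance*factor."""
    weighted = abundance * factors
    expected = abundance.sum()
    if expected <= 0:
        return np.zeros(len(abundance), dtype=np.int64)
    lam = depth * weighted / expected
    return rng.poisson(lam).astype(np.int64)


def _assemble_map(
    genome: SyntheticGenome,
    chrom_idx: np.ndarray,
    pos: np.ndarray,
    reads: np.ndarray,
    sample_name: str,
) -> InsertionMap:
    chroms = sorted(genome.chrom_lengths)
    sites: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ci, chrom in enumerate(chroms):
        sel = (chrom_idx == ci) & (reads > 0)
        if sel.any():
            sites[chrom] = (pos[sel].astype(np.int64), reads[sel].astype(np.int64))
    return InsertionMap(sites=sites, sample_name=sample_name)


def simulate_library(
    genome: SyntheticGenome,
    truth: SyntheticTruth,
    depth: int,
    seed: int | np.random.Generator | None = None,
    sample_name: str = "sim",
) -> InsertionMap:
    """One full pass through placement, growth, bottleneck, PCR, sequencing."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(truth.seed if seed is None else seed)
    )
    chrom_idx, pos, mu = place_insertions(genome, truth, rng)
    abundance = grow_and_bottleneck(mu, truth.t, truth.bottleneck_per_site, rng)
    factors = pcr_factors(truth.alpha, len(abundance), rng)
    reads = sequence_reads(abundance, factors, depth, rng)
    return _assemble_map(genome, chrom_idx, pos, reads, sample_name)


def simulate_replicate_pair(
    genome: SyntheticGenome,
    truth: SyntheticTruth,
    depth: int,
    split_point: str,
    seed: int | np.random.Generator = 0,
) -> tuple[InsertionMap, InsertionMap]:
    """Two replicate libraries split at a chosen stage of the procedure.

    * ``expansion``: independent insertion placement, growth/bottleneck,
      PCR and sequencing (separate colonies -> separate libraries);
    * ``pcr``: shared mutant library and abundances, independent PCR
      amplification and sequencing (one DNA sample split before PCR);
    * ``sequencing``: shared PCR pool (shared read means), independent
      read sampling only (one amplified sample sequenced twice);
    * ``none``: identical replicate, returned twice.
    """
    if split_point not in SPLIT_POINTS:
        raise ValueError(f"split_point must be one of {SPLIT_POINTS}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if split_point == "expansion":
        a = simulate_library(genome, truth, depth, rng, sample_name="repA")
        b = simulate_library(genome, truth, depth, rng, sample_name="repB")
        return a, b
    chrom_idx, pos, mu = place_insertions(genome, truth, rng)
    abundance = grow_and_bottleneck(mu, truth.t, truth.bottleneck_per_site, rng)
    if split_point == "pcr":
        reads_a = sequence_reads(
            abundance, pcr_factors(truth.alpha, len(abundance), rng), depth, rng
        )
        reads_b = sequence_reads(
            abundance, pcr_factors(truth.alpha, len(abundance), rng), depth, rng
        )
    elif split_point == "sequencing":
        factors = pcr_factors(truth.alpha, len(abundance), rng)
        reads_a = sequence_reads(abundance, factors, depth, rng)
        reads_b = sequence_reads(abundance, factors, depth, rng)
    else:  # none
        factors = pcr_factors(truth.alpha, len(abundance), rng)
        reads_a = sequence_reads(abundance, factors, depth, rng)
        reads_b = reads_a.copy()
    a = _assemble_map(genome, chrom_idx, pos, reads_a, "repA")
    b = _assemble_map(genome, chrom_idx, pos, reads_b, "repB")
    return a, b


def write_truth_table(truth: SyntheticTruth, path) -> None:
    """Ground-truth TSV: gene_id, growth rate, scaled fitness."""
    w = truth.true_fitness()
    with open(path, "w") as fh:
        fh.write(f"# alpha={truth.alpha}\n# t={truth.t}\n# seed={truth.seed}\n")
        fh.write("gene_id\tgrowth_rate\ttrue_fitness\n")
        for gid in sorted(truth.growth_rate):
            fh.write(f"{gid}\t{truth.growth_rate[gid]!r}\t{w[gid]!r}\n")
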