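"""Per-gene fitness estimation from transposon insertion read counts.

The estimator rests on a Malthusian growth model for each insertion mutant,
N(t) = N(0) * 2^(mu*t) with N(0) = 1, so the read count at an insertion
site is a noisy proxy for 2^(mu*t). Averaging the read counts y_gi of the
sites mapped to a gene gives the per-gene statistic y_hat_g (the Poisson
MLE of the mutant's read level), and fitness is reported on two scales:

* median scale:      w_g = log2(y_hat_g) / median[log2(y_hat_g)]
* generation scale:  w_g = (y_hat_g / median[y_hat_g])^(1/t),  t = 10

Both scales normalise to the population median on the premise that most
gene disruptions are near-neutral. The per-gene read set is built in a
fixed order: assign sites to the gene, exclude insertions in the outer 10%
of the coding region (they often fail to knock the gene out), append
imputed zero-read sites for insertions the sequencing lost, trim
upper-tail outliers, then average. Genes with fewer than 5 usable sites,
or with only zeros left, are reported as status ``undetermined``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import centromere_bias, dispersion_model
from .config import RunConfig
from .genome_io import CentromereMap, GeneAnnotation, InsertionMap


@dataclass
class GeneReadProfile:
    """A gene's read-count sample at each pipeline stage.

    ``rel_positions`` are the coding-strand relative positions of the
    retained observed sites (in [edge, 1-edge)); imputed zero sites carry
    no position and are present only in ``reads``. ``o_full`` counts every
    observed insertion in the gene, edge-excluded ones included, and is
    the O(X_g) that imputation compares against E(X_g).
    """

    gene_id: str
    rel_positions: np.ndarray
    reads: np.ndarray
    n_observed: int          # retained observed sites (central region)
    n_edge_excluded: int
    o_full: int              # all observed sites in the gene
    expected_insertions: int = 0
    n_zero_imputed: int = 0
    n_trimmed: int = 0

    @property
    def n_after_trim(self) -> int:
        return len(self.reads)

    def sample_variance(self) -> float:
        """Unbiased (n-1) sample variance of the retained reads."""
        if len(self.reads) < 2:
            return float("nan")
        return float(np.var(self.reads, ddof=1))


@dataclass
class FitnessRecord:
    """Final per-gene estimate; written out by genome_io.write_fitness_table."""

    gene_id: str
    chrom: str
    n_observed: int
    expected_insertions: int
    n_zero_imputed: int
    n_used: int
    mean_reads: float
    fitness_median_scale: float
    fitness_generation_scale: float
    variance: float
    standard_error: float
    status: str
    essential: bool = False


def relative_position(gene: GeneAnnotation, position) -> np.ndarray:
    """Position along the coding strand as a fraction of gene length in [0, 1).

    On the + strand this is (pos - start)/L, on the - strand (end - pos)/L,
    so 0 is always the start codon side.
    """
    pos = np.asarray(position, dtype=float)
    if gene.strand == "+":
        rel = (pos - gene.start) / gene.length
    else:
        rel = (gene.end - pos) / gene.length
    return rel


def assign_and_filter(
    imap: InsertionMap, gene: GeneAnnotation, edge_fraction: float = 0.10
) -> GeneReadProfile:
    """Assign insertion sites to a gene and apply the edge exclusion.

    Sites with relative position in [edge_fraction, 1 - edge_fraction) are
    retained for the read average; edge sites are excluded from the read
    set but still counted in ``o_full`` for the imputation arithmetic.
    """
    pos, reads = imap.sites_in(gene.chrom, gene.start, gene.end)
    rel = relative_position(gene, pos)
    keep = (rel >= edge_fraction) & (rel < 1.0 - edge_fraction)
    return GeneReadProfile(
        gene_id=gene.gene_id,
        rel_positions=rel[keep],
        reads=reads[keep].astype(float),
        n_observed=int(keep.sum()),
        n_edge_excluded=int(len(pos) - keep.sum()),
        o_full=int(len(pos)),
    )


def impute_zero_sites(
    profile: GeneReadProfile, expected: int, full_gene: bool = True
) -> GeneReadProfile:
    """Append zero-read records for insertions presumed lost before sequencing.

    The number of zeros is max(0, E - O) with O the observed insertion count
    over the full gene by default (same denominator as E(X_g), which uses the
    full gene length); ``full_gene=False`` counts only central-region sites.
    """
    observed = profile.o_full if full_gene else profile.n_observed
    n_zero = centromere_bias.unobserved_sites(expected, observed)
    reads = np.concatenate([profile.reads, np.zeros(n_zero)])
    return replace(
        profile,
        reads=reads,
        expected_insertions=int(expected),
        n_zero_imputed=n_zero,
    )


def trim_outliers(
    profile: GeneReadProfile,
    multiplier: float = 1.5,
    percentiles: tuple[float, float] = (5.0, 95.0),
) -> GeneReadProfile:
    """Remove upper-tail outlier read counts.

    Reads exceeding q95 + multiplier*(q95 - q5) of the gene's read
    distribution (imputed zeros included, linear-interpolation percentiles)
    are dropped. The rule is upper-tail only: zeros are structural evidence
    of lost mutants and are never removed.
    """
    if len(profile.reads) == 0:
        return profile
    q_low, q_high = np.percentile(profile.reads, percentiles)
    threshold = q_high + multiplier * (q_high - q_low)
    keep = profile.reads <= threshold
    keep |= profile.reads == 0
    n_pos = len(profile.rel_positions)
    return replace(
        profile,
        rel_positions=profile.rel_positions[keep[:n_pos]],
        reads=profile.reads[keep],
        n_trimmed=int((~keep).sum()),
    )


def mean_reads(profile: GeneReadProfile) -> float:
    """y_hat_g: arithmetic mean of the retained read values, zeros included."""
    if len(profile.reads) == 0:
        return float("nan")
    return float(np.mean(profile.reads))


def fitness_median_scale(mean_reads_ok: np.ndarray) -> tuple[np.ndarray, float]:
    """Median-normalised log fitness for all determined genes at once.

    w_g = log2(y_hat_g) / mu_ref with mu_ref = median over determined genes
    of log2(y_hat_g). The ratio is invariant to the log base. Genes with
    y_hat < 1 get negative w. Raises if the median log is zero (median
    y_hat = 1), where the scaling is degenerate.
    """
    y = np.asarray(mean_reads_ok, dtype=float)
    if len(y) == 0 or np.any(y <= 0):
        raise ValueError("median-scale fitness needs determined genes with y_hat > 0")
    log_y = np.log2(y)
    mu_ref = float(np.median(log_y))
    if mu_ref == 0.0:
        raise ValueError("median log2 mean read count is 0; median scaling degenerate")
    return log_y / mu_ref, mu_ref


def fitness_generation_scale(
    mean_reads_g, median_mean_reads: float, t_gen: float = 10.0
) -> np.ndarray | float:
    """Generation-scaled fitness w_g = (y_hat_g / median[y_hat_g])^(1/t).

    This is the per-generation frequency-ratio scale used by competition
    assays, assuming every mutant starts from a single cell and the library
    expands for ``t_gen`` (default 10) generations. Equals 1 at the median
    and 0 at y_hat = 0.
    """
    if median_mean_reads <= 0:
        raise ValueError("median mean read count must be positive")
    y = np.asarray(mean_reads_g, dtype=float)
    w = (y / median_mean_reads) ** (1.0 / t_gen)
    return float(w) if np.isscalar(mean_reads_g) else w


@dataclass
class PipelineResult:
    records: list[FitnessRecord]
    profiles: dict[str, GeneReadProfile]
    dispersion: "dispersion_model.DispersionFit | None"
    bias_model: "centromere_bias.BiasModel | None"
    mu_ref: float
    median_mean_reads: float
    config: RunConfig = field(default_factory=RunConfig)


def estimate_fitness(
    imap: InsertionMap,
    genes: list[GeneAnnotation],
    cen: CentromereMap | None = None,
    bias_model: "centromere_bias.BiasModel | None" = None,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the full per-gene pipeline on one insertion map.

    Stages, in order: site assignment and edge exclusion; expected-count
    imputation of zero-read sites (needs centromeres; fitted from the data
    when no ``bias_model`` is passed); outlier trimming; mean read count;
    shared-dispersion fit; variance, SE, and both fitness scales.
    """
    cfg = config or RunConfig()
    if cfg.impute:
        if cen is None:
            raise ValueError("imputation requires a centromere map")
        if bias_model is None:
            curve = centromere_bias.cumulative_insertions(imap, cen, cfg.grid_step)
            bias_model = centromere_bias.fit_bias_model(
                curve, fit_range=cfg.fit_range, r_cut=cfg.r_cut
            )

    profiles: dict[str, GeneReadProfile] = {}
    for gene in genes:
        prof = assign_and_filter(imap, gene, cfg.edge_fraction)
        if cfg.impute:
            exp = centromere_bias.expected_insertions(gene, cen, bias_model)
            prof = impute_zero_sites(prof, exp, full_gene=cfg.impute_full_gene)
        elif cen is not None and bias_model is not None:
            # record E(X) even when not imputing (used by comparison filters)
            prof = replace(
                prof,
                expected_insertions=centromere_bias.expected_insertions(
                    gene, cen, bias_model
                ),
            )
        prof = trim_outliers(
            prof, cfg.outlier_multiplier, (cfg.percentile_low, cfg.percentile_high)
        )
        profiles[gene.gene_id] = prof

    means = {gid: mean_reads(p) for gid, p in profiles.items()}
    status = {
        gid: "ok"
        if p.n_after_trim >= cfg.min_usable_sites and np.nansum(p.reads) > 0
        else "undetermined"
        for gid, p in profiles.items()
    }
    ok_ids = [g.gene_id for g in genes if status[g.gene_id] == "ok"]
    if not ok_ids:
        raise ValueError("no gene has a determined fitness; cannot normalise")

    ok_means = np.array([means[gid] for gid in ok_ids])
    w_median, mu_ref = fitness_median_scale(ok_means)
    w_median_by_id = dict(zip(ok_ids, w_median))
    median_y = float(np.median(ok_means))
    w_gen = fitness_generation_scale(ok_means, median_y, cfg.t_gen)
    w_gen_by_id = dict(zip(ok_ids, np.atleast_1d(w_gen)))

    if not cfg.zeros_in_variance:
        var_profiles = {
            gid: replace(p, reads=p.reads[p.reads > 0]) for gid, p in profiles.items()
        }
    else:
        var_profiles = profiles
    fit = dispersion_model.fit_alpha(
        [var_profiles[gid] for gid in ok_ids], means={gid: means[gid] for gid in ok_ids}
    )

    records: list[FitnessRecord] = []
    for gene in genes:
        gid = gene.gene_id
        prof = profiles[gid]
        if status[gid] == "ok":
            y = means[gid]
            s2 = var_profiles[gid].sample_variance()
            v = dispersion_model.gene_variance(y, s2, fit)
            se = dispersion_model.standard_error(v, prof.n_after_trim)
            rec = FitnessRecord(
                gene_id=gid,
                chrom=gene.chrom,
                n_observed=prof.n_observed,
                expected_insertions=prof.expected_insertions,
                n_zero_imputed=prof.n_zero_imputed,
                n_used=prof.n_after_trim,
                mean_reads=y,
                fitness_median_scale=float(w_median_by_id[gid]),
                fitness_generation_scale=float(w_gen_by_id[gid]),
                variance=v,
                standard_error=se,
                status="ok",
                essential=gene.essential,
            )
        else:
            rec = FitnessRecord(
                gene_id=gid,
                chrom=gene.chrom,
                n_observed=prof.n_observed,
                expected_insertions=prof.expected_insertions,
                n_zero_imputed=prof.n_zero_imputed,
                n_used=prof.n_after_trim,
                mean_reads=float("nan"),
                fitness_median_scale=float("nan"),
                fitness_generation_scale=float("nan"),
                variance=float("nan"),
                standard_error=float("nan"),
                status="undetermined",
                essential=gene.essential,
            )
        records.append(rec)
    return PipelineResult(
        records=records,
        profiles=profiles,
        dispersion=fit,
        bias_model=bias_model,
        mu_ref=mu_ref,
        median_mean_reads=median_y,
        config=cfg,
    )
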