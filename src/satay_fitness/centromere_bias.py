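"""Pericentromeric insertion-bias model.

The MiniDS transposon used in SATAY preferentially reinserts close to its
excision site next to the centromere, so the genome-wide insertion rate is
elevated within roughly 200 kb of each centromere. To correct for this when
estimating how many insertion sites a gene *should* carry, the cumulative
number of insertions is accumulated as a function of centromere distance
r_c (averaged over all chromosome arms), a cubic polynomial is fitted to
the averaged curve over 0-400 kb, and the bias-corrected insertion rate
lambda(r_c) is the derivative of that fit for r_c < 200 kb, held constant
at lambda(200 kb) beyond:

    lambda(r_c) = a1 + 2*a2*r_c + 3*a3*r_c^2     for r_c <  r_cut
    lambda(r_c) = lambda(r_cut)                  for r_c >= r_cut

The expected insertion count of a gene is E(X_g) = floor(lambda(r_cg) * L_g)
with r_cg the distance from the gene center to the nearer centromere edge,
and the number of unobserved (zero-read) sites is max(0, E - O).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genome_io import CentromereMap, GeneAnnotation, InsertionMap

#: internal abscissa rescaling for the polynomial fit (bp). Fitting the cubic
#: directly in bp makes the design matrix numerically singular (r^3 ~ 1e17);
#: the fit runs on r/R_SCALE and coefficients are converted back to bp units.
R_SCALE = 1e5


class BiasFitError(ValueError):
    """The fitted insertion-rate model is unusable (e.g. negative rate)."""


@dataclass
class CumulativeCurve:
    """Cumulative insertion counts against centromere distance.

    ``arm_counts[arm]`` holds, for each grid distance, the number of
    insertions on that arm within that distance, NaN beyond the arm's
    extent. ``mean_counts`` averages, at each distance, over the arms
    still defined there.
    """

    grid: np.ndarray
    arm_counts: dict[str, np.ndarray]
    mean_counts: np.ndarray
    grid_step: int

    @property
    def max_distance(self) -> int:
        return int(self.grid[-1]) if len(self.grid) else 0


@dataclass
class BiasModel:
    """Fitted cumulative-count cubic and the piecewise rate lambda(r_c)."""

    coefficients: tuple[float, float, float, float]  # a0..a3, bp units
    r_cut: int
    lambda_plateau: float
    rss: float
    fit_range: int

    def rate(self, r_c) -> np.ndarray | float:
        """Bias-corrected insertion rate (bp^-1) at centromere distance r_c."""
        r = np.asarray(r_c, dtype=float)
        _, a1, a2, a3 = self.coefficients
        lam = a1 + 2.0 * a2 * r + 3.0 * a3 * r * r
        out = np.where(r >= self.r_cut, self.lambda_plateau, lam)
        return float(out) if np.isscalar(r_c) else out


def site_centromere_distances(
    imap: InsertionMap, cen: CentromereMap
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per chromosome, split sites into (left-arm, right-arm) distance arrays.

    A site left of the centromere has distance cen_start - position, a site
    right of it position - cen_end; sites inside the interval get distance 0
    and are assigned to the left arm by convention.
    """
    missing = [c for c in imap.chromosomes if c not in cen]
    if missing:
        raise ValueError(f"chromosomes without centromere entry: {missing}")
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in imap.chromosomes:
        cen_start, cen_end = cen[chrom]
        pos = imap.positions(chrom)
        left = cen_start - pos[pos <= cen_end]
        left = np.clip(left, 0, None)
        right = pos[pos > cen_end] - cen_end
        out[chrom] = (left, right)
    return out


def cumulative_insertions(
    imap: InsertionMap, cen: CentromereMap, grid_step: int = 1_000
) -> CumulativeCurve:
    """Cumulative insertion count per arm on a regular distance grid.

    Each chromosome contributes its two arms. The averaged curve at
    distance r is the mean over all arms whose extent (largest observed
    site distance) is >= r, so short arms never truncate the tail.
    """
    arms = site_centromere_distances(imap, cen)
    arm_dist: dict[str, np.ndarray] = {}
    for chrom, (left, right) in arms.items():
        arm_dist[f"{chrom}:left"] = np.sort(left)
        arm_dist[f"{chrom}:right"] = np.sort(right)
    arm_dist = {k: v for k, v in arm_dist.items() if len(v)}
    if not arm_dist:
        return CumulativeCurve(
            grid=np.array([], dtype=np.int64),
            arm_counts={},
            mean_counts=np.array([]),
            grid_step=grid_step,
        )
    max_dist = max(int(v[-1]) for v in arm_dist.values())
    grid = np.arange(0, max_dist + grid_step, grid_step, dtype=np.int64)
    arm_counts: dict[str, np.ndarray] = {}
    for arm, dist in arm_dist.items():
        counts = np.searchsorted(dist, grid, side="right").astype(float)
        counts[grid > dist[-1]] = np.nan  # beyond this arm's extent
        arm_counts[arm] = counts
    stacked = np.vstack(list(arm_counts.values()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_counts = np.nanmean(stacked, axis=0)
    return CumulativeCurve(
        grid=grid, arm_counts=arm_counts, mean_counts=mean_counts, grid_step=grid_step
    )


def fit_bias_model(
    curve: CumulativeCurve, fit_range: int = 400_000, r_cut: int = 200_000
) -> BiasModel:
    """Least-squares cubic fit of the arm-averaged cumulative curve.

    The fit uses grid points within ``fit_range`` (warning if the curve is
    shorter), unweighted. The insertion rate is the derivative of the fit
    below ``r_cut`` and constant beyond; by construction lambda is
    continuous at ``r_cut``. A rate that dips below zero anywhere on
    [0, r_cut] raises :class:`BiasFitError`.
    """
    mask = (curve.grid <= fit_range) & np.isfinite(curve.mean_counts)
    r = curve.grid[mask].astype(float)
    y = curve.mean_counts[mask]
    if len(r) < 4:
        raise BiasFitError(f"only {len(r)} grid points available for the cubic fit")
    if curve.max_distance < fit_range:
        warnings.warn(
            f"cumulative curve extends only to {curve.max_distance} bp; "
            f"fitting on the available range instead of {fit_range} bp",
            stacklevel=2,
        )
    x = r / R_SCALE
    design = np.vander(x, 4, increasing=True)
    coef_scaled, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    coef = tuple(float(c / R_SCALE**k) for k, c in enumerate(coef_scaled))
    rss = float(np.sum((design @ coef_scaled - y) ** 2))
    _, a1, a2, a3 = coef
    lam_plateau = a1 + 2.0 * a2 * r_cut + 3.0 * a3 * r_cut**2
    model = BiasModel(
        coefficients=coef,
        r_cut=r_cut,
        lambda_plateau=float(lam_plateau),
        rss=rss,
        fit_range=fit_range,
    )
    _validate_rate_nonnegative(model)
    return model


def _validate_rate_nonnegative(model: BiasModel) -> None:
    # lambda on [0, r_cut] is a parabola: check endpoints and the vertex.
    _, a1, a2, a3 = model.coefficients
    candidates = [0.0, float(model.r_cut)]
    if a3 != 0.0:
        vertex = -a2 / (3.0 * a3)
        if 0.0 < vertex < model.r_cut:
            candidates.append(vertex)
    lam = [a1 + 2.0 * a2 * r + 3.0 * a3 * r * r for r in candidates]
    if min(lam) < 0.0:
        raise BiasFitError(
            "fitted insertion rate is negative within the fit range; "
            "inspect the cumulative insertion curve"
        )


def gene_centromere_distance(gene: GeneAnnotation, cen: CentromereMap) -> int:
    """Distance (bp) from the gene center to the nearer centromere edge."""
    if gene.chrom not in cen:
        raise ValueError(f"no centromere for chromosome {gene.chrom!r}")
    cen_start, cen_end = cen[gene.chrom]
    center = gene.center
    if center < cen_start:
        return cen_start - center
    if center > cen_end:
        return center - cen_end
    return 0


def expected_insertions(
    gene: GeneAnnotation, cen: CentromereMap, model: BiasModel
) -> int:
    """E(X_g) = floor(lambda(r_cg) * L_g), over the full gene length."""
    lam = model.rate(gene_centromere_distance(gene, cen))
    return int(np.floor(lam * gene.length))


def unobserved_sites(expected: int, observed: int) -> int:
    """Number of zero-read sites to impute: max(0, E - O).

    When observed insertions exceed their expectation, no unobserved
    sites are presumed to exist.
    """
    if expected < 0 or observed < 0:
        raise ValueError("expected and observed counts must be non-negative")
    return max(0, int(expected) - int(observed))
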