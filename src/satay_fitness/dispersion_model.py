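"""Shared negative-binomial overdispersion from the mean-variance relationship.

Read counts at the insertion sites of one gene are modelled as negative
binomial with Var(Y) = mu + alpha*mu^2; alpha = 0 recovers the Poisson.
A single alpha is shared by all genes of a dataset (all counts are
conditional on the same sequencing depth), estimated by ordinary least
squares on the regression form

    (s2_g - y_hat_g) / y_hat_g = alpha * y_hat_g

i.e. the no-intercept OLS slope of the excess-variance ratio on the gene
mean. Per-gene variances then take the maximum of the fitted trend and
the gene's own sample variance, and SE_g = sqrt(V_g / n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import statsmodels.api as sm


@dataclass
class DispersionFit:
    """Fitted shared overdispersion and regression diagnostics."""

    alpha: float
    n_genes: int
    slope_raw: float       # OLS slope before clamping at 0
    rsquared: float


def fit_alpha(
    profiles: Sequence | None = None,
    means: Mapping[str, float] | None = None,
    mean_values: Iterable[float] | None = None,
    variances: Iterable[float] | None = None,
    min_genes: int = 10,
) -> DispersionFit:
    """Estimate the shared overdispersion alpha.

    Accepts either gene read profiles (``profiles``, optionally with a
    precomputed ``means`` mapping by gene_id) or raw ``mean_values`` /
    ``variances`` arrays. Genes contribute when they have at least two
    retained sites and a positive mean. A negative OLS slope is clamped to
    0 (the Poisson limit) with a warning.
    """
    if profiles is not None:
        y_list, s2_list = [], []
        for prof in profiles:
            if prof.n_after_trim < 2:
                continue
            y = (
                means[prof.gene_id]
                if means is not None
                else float(np.mean(prof.reads))
            )
            if not np.isfinite(y) or y <= 0:
                continue
            s2 = prof.sample_variance()
            if not np.isfinite(s2):
                continue
            y_list.append(y)
            s2_list.append(s2)
        y_arr = np.asarray(y_list, dtype=float)
        s2_arr = np.asarray(s2_list, dtype=float)
    else:
        y_arr = np.asarray(list(mean_values), dtype=float)
        s2_arr = np.asarray(list(variances), dtype=float)
        ok = np.isfinite(y_arr) & np.isfinite(s2_arr) & (y_arr > 0)
        y_arr, s2_arr = y_arr[ok], s2_arr[ok]

    if len(y_arr) < min_genes:
        raise ValueError(
            f"only {len(y_arr)} usable genes for the dispersion fit "
            f"(need >= {min_genes})"
        )
    z = (s2_arr - y_arr) / y_arr
    result = sm.OLS(z, y_arr).fit()
    slope = float(result.params[0])
    alpha = slope
    if alpha < 0.0:
        warnings.warn(
            f"overdispersion OLS slope {alpha:.3g} < 0; clamping to the "
            "Poisson limit alpha = 0",
            stacklevel=2,
        )
        alpha = 0.0
    return DispersionFit(
        alpha=alpha,
        n_genes=len(y_arr),
        slope_raw=slope,
        rsquared=float(result.rsquared),
    )


def trend_variance(mean_reads: float, alpha: float) -> float:
    """Negative-binomial trend variance mu + alpha*mu^2."""
    return float(mean_reads + alpha * mean_reads**2)


def gene_variance(mean_reads: float, sample_variance: float, fit: DispersionFit) -> float:
    """V_g = max(trend, sample): never underestimate a gene's own spread."""
    trend = trend_variance(mean_reads, fit.alpha)
    if not np.isfinite(sample_variance):
        return trend
    return float(max(trend, sample_variance))


def standard_error(variance: float, n_sites: int) -> float:
    """SE_g = sqrt(V_g / n) with n the sites used for the gene's mean."""
    if n_sites < 1:
        raise ValueError("standard error needs at least one site")
    return float(np.sqrt(variance / n_sites))
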