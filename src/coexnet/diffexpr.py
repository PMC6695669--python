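"""Moderated two-group differential expression.

Per-gene two-sample comparisons on a handful of arrays are unstable because
each gene's variance is estimated from few residual degrees of freedom.
The empirical-Bayes remedy assumes the true gene variances follow a scaled
inverse-chi-square prior with d0 degrees of freedom and scale s0^2, fitted
by moment matching on the log sample variances; each gene's variance is
then shrunk toward s0^2 and the resulting moderated t-statistic gains
d0 extra degrees of freedom.  In the limits this recovers the ordinary
pooled t (d0 = 0) and a common-variance z-like test (d0 = infinity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .datatypes import ExpressionMatrix, SampleGroups
from .overlap import NamedEntityList


class DiffExprError(ValueError):
    pass


@dataclass
class EBayesParams:
    """Prior df (d0, may be inf) and prior variance (s0_sq) of the variance prior."""

    d0: float
    s0_sq: float


@dataclass
class DEResult:
    gene_id: str
    mean_diff: float          # case - control, log-units
    ordinary_t: float
    moderated_t: float
    p_value: float
    adj_p_value: float
    degenerate: bool = False  # constant in both groups with d0 = 0


def _trigamma_inverse(y: float, tol: float = 1e-8) -> float:
    """Solve trigamma(x) = y for x > 0 by monotone bisection."""
    if y <= 0:
        return math.inf
    lo, hi = 1e-12, 1.0
    while special.polygamma(1, hi) > y:
        hi *= 2.0
        if hi > 1e12:
            return hi
    while special.polygamma(1, lo) < y:
        lo /= 2.0
    while hi - lo > tol * max(1.0, lo):
        mid = 0.5 * (lo + hi)
        if special.polygamma(1, mid) > y:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def estimate_eb_params(residual_variances: np.ndarray, residual_df: int) -> EBayesParams:
    """Moment-matching fit of the variance prior on log sample variances.

    With s_g^2 ~ s0^2 * F(d, d0), the variance of log s_g^2 exceeds the
    trigamma(d/2) contribution of the data by trigamma(d0/2); inverting the
    trigamma recovers d0, and the mean of log s_g^2 then fixes s0^2.  When
    the empirical excess spread is <= 0 the prior is degenerate (d0 = inf)
    and s0^2 is the geometric mean variance.
    """
    s2 = np.asarray(residual_variances, dtype=float)
    if s2.size < 2:
        raise DiffExprError("need variances from at least 2 genes")
    if np.any(s2 <= 0):
        raise DiffExprError("all residual variances must be positive")
    d = int(residual_df)
    if d < 1:
        raise DiffExprError("residual_df must be >= 1")
    z = np.log(s2)
    mean_z = float(np.mean(z))
    var_z = float(np.var(z, ddof=1))
    excess = var_z - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        return EBayesParams(d0=math.inf, s0_sq=float(np.exp(mean_z)))
    d0 = 2.0 * _trigamma_inverse(excess)
    log_s0_sq = (
        mean_z
        - float(special.digamma(d / 2.0)) + math.log(d / 2.0)
        + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
    )
    return EBayesParams(d0=d0, s0_sq=float(np.exp(log_s0_sq)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise DiffExprError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise DiffExprError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return np.maximum(out, p)  # guard the adj >= raw invariant against rounding


def moderated_t_test(
    matrix: ExpressionMatrix,
    groups: SampleGroups,
    eb_params: EBayesParams | None = None,
) -> list[DEResult]:
    """Per-gene moderated t-test of case vs control.

    The pooled within-group variance is shrunk toward the empirical-Bayes
    prior, s_post^2 = (d0 s0^2 + d s^2) / (d0 + d), and the two-sided
    p-value uses d0 + d degrees of freedom.  `eb_params` can be forced
    (e.g. d0 = 0 for the ordinary t) — otherwise it is estimated from the
    data.  Genes constant in both groups with d0 = 0 have an undefined
    statistic and are reported with p = 1 and a degeneracy flag.
    """
    groups.validate_against(matrix)
    case = groups.mask(matrix, SampleGroups.CASE)
    ctrl = groups.mask(matrix, SampleGroups.CONTROL)
    n1, n2 = int(case.sum()), int(ctrl.sum())
    if n1 < 2 or n2 < 2:
        raise DiffExprError("both groups need >= 2 samples")
    x1, x2 = matrix.values[:, case], matrix.values[:, ctrl]
    diff = x1.mean(axis=1) - x2.mean(axis=1)
    d = n1 + n2 - 2
    pooled = ((n1 - 1) * x1.var(axis=1, ddof=1) + (n2 - 1) * x2.var(axis=1, ddof=1)) / d
    se_factor = math.sqrt(1.0 / n1 + 1.0 / n2)

    if eb_params is None:
        positive = pooled[pooled > 0]
        if positive.size < 2:
            raise DiffExprError("too few genes with positive variance to fit the prior")
        eb_params = estimate_eb_params(positive, d)
    d0, s0_sq = eb_params.d0, eb_params.s0_sq

    with np.errstate(divide="ignore", invalid="ignore"):
        ordinary_t = diff / (np.sqrt(pooled) * se_factor)
    if math.isinf(d0):
        s_post = np.full_like(pooled, s0_sq)
        df_total = np.inf
    else:
        s_post = (d0 * s0_sq + d * pooled) / (d0 + d)
        df_total = d0 + d

    degenerate = s_post <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        mod_t = diff / (np.sqrt(s_post) * se_factor)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(mod_t))
    else:
        p = 2.0 * stats.t.sf(np.abs(mod_t), df=df_total)
    mod_t = np.where(degenerate, 0.0, mod_t)
    p = np.where(degenerate, 1.0, p)
    ordinary_t = np.nan_to_num(ordinary_t, nan=0.0, posinf=np.inf, neginf=-np.inf)
    adj = bh_adjust(p)
    return [
        DEResult(
            gene_id=g,
            mean_diff=float(diff[i]),
            ordinary_t=float(ordinary_t[i]),
            moderated_t=float(mod_t[i]),
            p_value=float(p[i]),
            adj_p_value=float(adj[i]),
            degenerate=bool(degenerate[i]),
        )
        for i, g in enumerate(matrix.gene_ids)
    ]


def select_network_genes(
    de_results: list[DEResult],
    curated_gwas: NamedEntityList | None,
    matrix_genes: list[str],
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> list[str]:
    """Genes entering network inference: DE at `alpha` or curated GWAS hits.

    The union of genes with (raw, or adjusted when requested) p below alpha
    and curated GWAS genes present in the matrix, in matrix order.  An
    empty result is an error suggesting a larger alpha.
    """
    if not 0.0 < alpha < 1.0:
        raise DiffExprError(f"alpha must be in (0, 1), got {alpha}")
    de_genes = {
        r.gene_id
        for r in de_results
        if (r.adj_p_value if use_adjusted else r.p_value) < alpha
    }
    gwas = curated_gwas.tokens() if curated_gwas is not None else set()
    present = set(matrix_genes)
    chosen = (de_genes | (gwas & present)) & present
    if not chosen:
        raise DiffExprError(
            f"no genes selected at alpha={alpha} and no curated GWAS genes in the "
            "matrix; consider a larger alpha"
        )
    return [g for g in matrix_genes if g in chosen]
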