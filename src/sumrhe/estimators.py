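"""SNP-heritability estimators: exact HE, randomized HE, and the
summary-statistics reconstruction.

All three solve the same Haseman-Elston method-of-moments normal equations

    [tr(K^2)  tr(K)] [sg2]   [y'Ky]
    [tr(K)    N    ] [se2] = [y'y ]

for standardized X and y (tr(K) = N, y'y = N), giving

    h2 = (y'Ky / y'y - 1) / (tr(K^2)/N - 1).

They differ only in where the two data-dependent quantities come from:

* HE_EXACT  -- y'Ky = ||X'y||^2 / M and tr(K^2) computed exactly;
* RHE       -- tr(K^2) replaced by the Hutchinson stochastic estimate;
* SUM_RHE   -- y'Ky/y'y reconstructed from GWAS summary statistics via the
  adjusted z-scores (N z'z / M = y'Ky / y'y) and tr(K^2) supplied by a
  reference trace summary through N rho = tr(K^2)/N - 1, i.e.
  h2 = (N z'z / M - 1) / (N rho).

Standard errors come from a leave-one-SNP-block-out jackknife in which the
numerator and the trace are recomputed for each left-out block with
M_jack = M - m_block renormalization.  Estimates are never clamped to
[0, 1]: under a null phenotype roughly half of them must come out negative
for the one-sided calibration test to hold its level.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats as sps

from .genotype_io import StandardizedGenotypes
from .gwas import GwasSumstats, adjusted_z
from .trace import (
    TraceCompatibilityError,
    TraceSummary,
    make_trace_summary,
    snp_digest,
)

METHOD_HE_EXACT = "HE_EXACT"
METHOD_RHE = "RHE"
METHOD_SUM_RHE = "SUM_RHE"


class EstimatorError(ValueError):
    """Degenerate inputs to a heritability estimator."""


@dataclasses.dataclass
class HeritabilityEstimate:
    h2: float
    se: float
    n_blocks: int
    method: str
    m: int
    n: int
    sigma_g2: float | None = None
    sigma_e2: float | None = None
    replicates: np.ndarray | None = None

    def report_line(self) -> str:
        return f"{self.method}\t{self.h2:.6g}\t{self.se:.6g}\t{self.n_blocks}\t{self.m}\t{self.n}"


@dataclasses.dataclass
class NullTestResult:
    statistic: float
    p_value: float
    reject: bool
    alpha: float


def jackknife_se(replicates, point: float | None = None) -> float:
    """Delete-one-block jackknife SE: sqrt((n-1)/n * sum_i (h_i - mean)^2)."""
    r = np.asarray(replicates, dtype=np.float64)
    nb = r.size
    if nb < 2:
        raise ValueError("jackknife needs at least 2 block replicates")
    dev = r - r.mean()
    return float(np.sqrt((nb - 1) / nb * float(dev @ dev)))


def test_null(est: HeritabilityEstimate, alpha: float = 0.05) -> NullTestResult:
    """One-sided normal test of h2 > 0: p = 1 - Phi(h2 / se), reject iff p < alpha."""
    if est.se <= 0.0:
        raise EstimatorError("degenerate test: standard error must be positive")
    stat = est.h2 / est.se
    p = float(sps.norm.sf(stat))
    return NullTestResult(statistic=stat, p_value=p, reject=p < alpha, alpha=alpha)


def _check_standardized_y(y: np.ndarray, n: int) -> float:
    yy = float(y @ y)
    if abs(yy / n - 1.0) > 1e-6:
        raise EstimatorError("phenotype must be standardized (y'y = N)")
    return yy


def _individual_mom(
    geno: StandardizedGenotypes,
    y: np.ndarray,
    trace: TraceSummary,
    method: str,
) -> HeritabilityEstimate:
    """HE normal-equation solve given any (exact or stochastic) trace summary."""
    x = geno.matrix
    n, m = x.shape
    if trace.m != m or trace.n_ref != n or trace.digest != snp_digest(geno.snp_ids):
        raise TraceCompatibilityError("trace summary was not computed on this panel")
    y = np.asarray(y, dtype=np.float64)
    if y.size != n:
        raise EstimatorError(f"phenotype length {y.size} != sample count {n}")
    yy = _check_standardized_y(y, n)
    if trace.rho <= 0.0:
        raise EstimatorError(
            "non-positive trace summary rho (tr(K^2) <= N); "
            "increase probe count or SNP panel size"
        )

    u = x.T @ y
    uu = float(u @ u)
    yky = uu / m
    h2 = (yky / yy - 1.0) / (n * trace.rho)
    sigma_g2 = (yky - yy) / (n * n * trace.rho)
    sigma_e2 = yy / n - sigma_g2

    reps = np.empty(trace.n_blocks)
    for k, (sl, blk) in enumerate(zip(trace.block_slices(), trace.blocks)):
        if blk.rho_jack <= 0.0:
            raise EstimatorError(f"non-positive jackknife rho in block {blk.index}")
        ub = u[sl]
        yky_b = (uu - float(ub @ ub)) / (m - blk.m_block)
        reps[k] = (yky_b / yy - 1.0) / (n * blk.rho_jack)
    se = jackknife_se(reps)

    return HeritabilityEstimate(
        h2=float(h2), se=se, n_blocks=trace.n_blocks, method=method, m=m, n=n,
        sigma_g2=float(sigma_g2), sigma_e2=float(sigma_e2), replicates=reps,
    )


def estimate_he_exact(
    geno: StandardizedGenotypes,
    y: np.ndarray,
    n_blocks: int = 100,
    trace: TraceSummary | None = None,
) -> HeritabilityEstimate:
    """Exact HE method-of-moments estimate (forms the M x M Gram matrix;
    intended for panels of at most a few thousand SNPs).

    A precomputed exact-mode trace summary for this panel may be passed to
    amortize the Gram computation across phenotypes.
    """
    if trace is None:
        n_blocks = min(n_blocks, geno.m)
        trace = make_trace_summary(geno, n_blocks=n_blocks, exact=True)
    elif trace.b_total != 0:
        raise EstimatorError("estimate_he_exact requires an exact-mode trace (b_total = 0)")
    return _individual_mom(geno, y, trace, METHOD_HE_EXACT)


def estimate_rhe(
    geno: StandardizedGenotypes,
    y: np.ndarray,
    b: int = 100,
    n_blocks: int = 100,
    seed=None,
    trace: TraceSummary | None = None,
) -> HeritabilityEstimate:
    """Randomized HE: the exact trace is replaced by a Hutchinson estimate
    with ``b`` standard-normal probes (fresh per call unless ``trace`` is
    supplied)."""
    if trace is None:
        trace = make_trace_summary(geno, b=b, n_blocks=min(n_blocks, geno.m), seed=seed)
    return _individual_mom(geno, y, trace, METHOD_RHE)


def estimate_sumrhe(
    stats: GwasSumstats,
    trace: TraceSummary,
    n_target: int | None = None,
    intersect: bool = False,
) -> HeritabilityEstimate:
    """Summary-statistics heritability: h2 = (N z'z / M - 1) / (N rho).

    ``n_target`` is the GWAS sample size N (defaults to stats.n_total).  The
    sumstats SNP list must match the trace summary's SNP set; with
    ``intersect`` the estimate is formed on the intersection instead (the
    released rho values then refer to a superset panel -- loudly warned).
    """
    trace.validate()
    n = int(n_target) if n_target is not None else int(stats.n_total)
    if n <= 1:
        raise EstimatorError("target sample size N must exceed 1")
    if trace.rho <= 0.0:
        raise EstimatorError("non-positive trace summary rho; invalid trace")

    assignment = np.repeat(
        np.arange(trace.n_blocks), [blk.m_block for blk in trace.blocks]
    )
    matches = stats.m == trace.m and (
        trace.snp_ids is None or snp_digest(stats.ids) == trace.digest
    )
    if matches:
        z = adjusted_z(stats, n).z
        m_eff = trace.m
    elif intersect:
        if trace.snp_ids is None:
            raise TraceCompatibilityError(
                "cannot intersect: trace summary carries no SNP id list"
            )
        pos = {sid: j for j, sid in enumerate(stats.ids)}
        keep_trace = [j for j, sid in enumerate(trace.snp_ids) if sid in pos]
        if not keep_trace:
            raise TraceCompatibilityError("no SNPs shared between sumstats and trace")
        warnings.warn(
            f"intersecting sumstats with trace summary: using {len(keep_trace)} of "
            f"{trace.m} trace SNPs; released rho values refer to the full panel"
        )
        order = [pos[trace.snp_ids[j]] for j in keep_trace]
        sub = GwasSumstats(
            ids=[stats.ids[i] for i in order],
            beta=stats.beta[order],
            se=stats.se[order],
            obs_ct=stats.obs_ct[order],
            n_total=stats.n_total,
        )
        z = adjusted_z(sub, n).z
        m_eff = len(keep_trace)
        assignment = assignment[keep_trace]
    else:
        raise TraceCompatibilityError(
            f"sumstats SNP set (M={stats.m}) does not match trace summary "
            f"(M={trace.m}); pass intersect=True to estimate on the overlap"
        )

    zz = float(z @ z)
    h2 = (n * zz / m_eff - 1.0) / (n * trace.rho)

    reps = np.empty(trace.n_blocks)
    for k, blk in enumerate(trace.blocks):
        if blk.rho_jack <= 0.0:
            raise EstimatorError(f"non-positive jackknife rho in block {blk.index}")
        zb = z[assignment == k]
        zz_b = zz - float(zb @ zb)
        m_jack = m_eff - zb.size
        if m_jack <= 0:
            raise EstimatorError("jackknife block spans the whole SNP panel")
        reps[k] = (n * zz_b / m_jack - 1.0) / (n * blk.rho_jack)
    se = jackknife_se(reps)

    return HeritabilityEstimate(
        h2=float(h2), se=se, n_blocks=trace.n_blocks, method=METHOD_SUM_RHE,
        m=m_eff, n=n, replicates=reps,
    )
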