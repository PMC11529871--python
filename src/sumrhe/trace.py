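"""Trace of the squared genetic relatedness matrix and shareable trace summaries.

For standardized genotypes X (N x M) and K = XX'/M, tr(K^2) drives the
denominator of the Haseman-Elston method-of-moments estimator.  This module
computes it three ways:

* exactly via the M x M Gram route, tr((X'X)^2)/M^2 (small-panel oracle);
* stochastically via Hutchinson probes, mean_b ||X(X'z_b)||^2 / M^2, which
  is unbiased and costs O(MNB) without ever forming K;
* as a *trace summary*: the population statistic rho = (tr(K^2)/N - 1)/N
  (interpretable as the average LD across SNPs) together with
  leave-one-SNP-block-out jackknife values, the artifact a reference cohort
  can release so that downstream users never need its genotypes.

Leave-one-out values reuse the same probe vectors as the full run and are
exactly equal to a physical re-computation on the subset panel.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
from pathlib import Path

import numpy as np

from .genotype_io import StandardizedGenotypes

TRACE_VERSION = 1


class TraceFormatError(ValueError):
    """Malformed trace-summary file."""


class TraceCompatibilityError(ValueError):
    """Trace summaries (or a trace and sumstats) that cannot be combined."""


def snp_digest(ids) -> str:
    """Order-sensitive SHA-256 digest of a SNP id list."""
    return hashlib.sha256("\n".join(ids).encode()).hexdigest()


def jackknife_plan(m: int, n_blocks: int) -> list[slice]:
    """Contiguous SNP blocks of floor(M/n) SNPs, remainder on the last block."""
    if n_blocks < 2:
        raise ValueError("need at least 2 jackknife blocks")
    if n_blocks > m:
        raise ValueError(f"n_blocks={n_blocks} exceeds SNP count M={m}")
    size = m // n_blocks
    starts = [k * size for k in range(n_blocks)]
    ends = starts[1:] + [m]
    return [slice(a, b) for a, b in zip(starts, ends)]


@dataclasses.dataclass(frozen=True)
class JackknifeBlock:
    index: int
    m_block: int
    rho_jack: float


@dataclasses.dataclass
class TraceSummary:
    """Shareable reference statistic: rho plus per-block jackknife values.

    ``b_total`` counts the random probe vectors aggregated into the estimate
    (0 means the trace was computed exactly).
    """

    n_ref: int
    m: int
    b_total: int
    rho: float
    blocks: list[JackknifeBlock]
    digest: str
    snp_ids: list[str] | None = None

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_slices(self) -> list[slice]:
        out, start = [], 0
        for blk in self.blocks:
            out.append(slice(start, start + blk.m_block))
            start += blk.m_block
        return out

    def validate(self) -> None:
        if sum(b.m_block for b in self.blocks) != self.m:
            raise TraceFormatError("sum of block SNP counts != M")
        if not self.blocks:
            raise TraceFormatError("trace summary has no jackknife blocks")


def _rho_from_trace(tr_k2: float, n: int) -> float:
    return (tr_k2 / n - 1.0) / n


def exact_trace_K2(geno: StandardizedGenotypes | np.ndarray) -> float:
    """tr(K^2) via the M x M Gram route: ||X'X||_F^2 / M^2."""
    x = geno.matrix if isinstance(geno, StandardizedGenotypes) else np.asarray(geno)
    m = x.shape[1]
    g = x.T @ x
    return float(np.einsum("ij,ij->", g, g)) / (m * m)


def exact_trace_K2_grm_route(geno: StandardizedGenotypes | np.ndarray) -> float:
    """tr(K^2) via the N x N route (forms K explicitly; oracle for tests)."""
    x = geno.matrix if isinstance(geno, StandardizedGenotypes) else np.asarray(geno)
    m = x.shape[1]
    k = (x @ x.T) / m
    return float(np.einsum("ij,ij->", k, k))


def _draw_probes(n: int, b: int, seed, rademacher: bool) -> np.ndarray:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if rademacher:
        return rng.integers(0, 2, size=(n, b)).astype(np.float64) * 2.0 - 1.0
    return rng.standard_normal((n, b))


def stochastic_trace_K2(
    geno: StandardizedGenotypes | np.ndarray,
    b: int,
    seed=None,
    probes: np.ndarray | None = None,
    rademacher: bool = False,
) -> float:
    """Hutchinson estimate of tr(K^2): mean_b ||X(X'z_b)||^2 / M^2.

    ``probes`` overrides the random draw (used by tests asserting exact
    agreement between shared-probe shortcuts and physical subsetting).
    """
    if b < 1:
        raise ValueError("need at least one probe vector")
    x = geno.matrix if isinstance(geno, StandardizedGenotypes) else np.asarray(geno)
    n, m = x.shape
    z = probes if probes is not None else _draw_probes(n, b, seed, rademacher)
    if z.shape != (n, b):
        raise ValueError(f"probes must have shape ({n}, {b})")
    u = x.T @ z
    w = x @ u
    return float(np.einsum("ij,ij->", w, w)) / (m * m * b)


def make_trace_summary(
    geno: StandardizedGenotypes,
    b: int = 100,
    n_blocks: int = 100,
    seed=None,
    exact: bool = False,
    rademacher: bool = False,
    probes: np.ndarray | None = None,
) -> TraceSummary:
    """Compute rho and its leave-one-block-out jackknife values.

    Each jackknife value excludes one contiguous SNP block and renormalizes
    by M_jack = M - m_block throughout; in stochastic mode the same probe
    vectors are reused across all leave-one-out evaluations, so each value
    equals the estimate on the physically subset panel with those probes.
    ``exact=True`` replaces the stochastic trace by the Gram-route exact
    trace (b is ignored; ``b_total`` is recorded as 0).
    """
    x = geno.matrix
    n, m = x.shape
    slices = jackknife_plan(m, n_blocks)

    if exact:
        g = x.T @ x
        gsq = g * g
        full = float(gsq.sum())
        row = gsq.sum(axis=1)
        tr_full = full / (m * m)
        tr_jack = []
        for sl in slices:
            mj = m - (sl.stop - sl.start)
            sub = full - 2.0 * float(row[sl].sum()) + float(gsq[sl, sl].sum())
            tr_jack.append(sub / (mj * mj))
        b_total = 0
    else:
        z = probes if probes is not None else _draw_probes(n, b, seed, rademacher)
        u = x.T @ z
        w = x @ u
        tr_full = float(np.einsum("ij,ij->", w, w)) / (m * m * b)
        tr_jack = []
        for sl in slices:
            wb = x[:, sl] @ u[sl]
            d = w - wb
            mj = m - (sl.stop - sl.start)
            tr_jack.append(float(np.einsum("ij,ij->", d, d)) / (mj * mj * b))
        b_total = b

    blocks = [
        JackknifeBlock(index=k, m_block=sl.stop - sl.start, rho_jack=_rho_from_trace(t, n))
        for k, (sl, t) in enumerate(zip(slices, tr_jack))
    ]
    return TraceSummary(
        n_ref=n,
        m=m,
        b_total=b_total,
        rho=_rho_from_trace(tr_full, n),
        blocks=blocks,
        digest=snp_digest(geno.snp_ids),
        snp_ids=list(geno.snp_ids),
    )


def make_trace_summary_runs(
    geno: StandardizedGenotypes,
    b: int = 100,
    runs: int = 25,
    n_blocks: int = 100,
    seed: int = 0,
) -> TraceSummary:
    """Aggregate ``runs`` independent stochastic runs of B probes each.

    Equivalent in expectation to a single run with B' = runs * B probes;
    per-run probe seeds are derived deterministically from ``seed``.
    """
    summaries = [
        make_trace_summary(
            geno, b=b, n_blocks=n_blocks, seed=np.random.default_rng([_as_int_seed(seed), i])
        )
        for i in range(runs)
    ]
    return aggregate_trace_runs(summaries)


def _as_int_seed(seed) -> int:
    if isinstance(seed, np.random.Generator):
        return int(seed.integers(0, 2**31 - 1))
    return int(seed)


def aggregate_trace_runs(summaries: list[TraceSummary]) -> TraceSummary:
    """Probe-count-weighted mean of rho and every rho_jack across runs."""
    if not summaries:
        raise ValueError("nothing to aggregate")
    head = summaries[0]
    sizes = [b.m_block for b in head.blocks]
    for s in summaries[1:]:
        if (s.n_ref, s.m, s.digest) != (head.n_ref, head.m, head.digest):
            raise TraceCompatibilityError("trace runs disagree on panel (n_ref, M, SNP digest)")
        if [b.m_block for b in s.blocks] != sizes:
            raise TraceCompatibilityError("trace runs disagree on jackknife block structure")
    weights = np.array([s.b_total for s in summaries], dtype=np.float64)
    if np.any(weights <= 0):
        raise TraceCompatibilityError("cannot aggregate exact-mode summaries (b_total = 0)")
    wsum = weights.sum()
    rho = float(np.dot(weights, [s.rho for s in summaries]) / wsum)
    blocks = []
    for k in range(head.n_blocks):
        rj = float(np.dot(weights, [s.blocks[k].rho_jack for s in summaries]) / wsum)
        blocks.append(JackknifeBlock(index=k, m_block=sizes[k], rho_jack=rj))
    return TraceSummary(
        n_ref=head.n_ref,
        m=head.m,
        b_total=int(wsum),
        rho=rho,
        blocks=blocks,
        digest=head.digest,
        snp_ids=head.snp_ids,
    )


def write_trace(summary: TraceSummary, path: str | Path) -> None:
    """Serialize to the text ``.trace`` format (17 significant digits)."""
    summary.validate()
    with Path(path).open("w") as fh:
        fh.write(f"#VERSION {TRACE_VERSION}\n")
        fh.write(f"#NREF {summary.n_ref}\n")
        fh.write(f"#M {summary.m}\n")
        fh.write(f"#B {summary.b_total}\n")
        fh.write(f"#RHO {summary.rho:.17g}\n")
        fh.write(f"#SNP_DIGEST {summary.digest}\n")
        for blk in summary.blocks:
            fh.write(f"{blk.index} {blk.m_block} {blk.rho_jack:.17g}\n")


def read_trace(
    path: str | Path,
    snp_ids: list[str] | None = None,
    strict: bool = True,
) -> TraceSummary:
    """Parse a ``.trace`` file, validating version, block totals and
    (optionally, against ``snp_ids``) the SNP digest."""
    path = Path(path)
    header: dict[str, str] = {}
    blocks: list[JackknifeBlock] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition(" ")
            header[key] = val.strip()
            continue
        parts = line.split()
        if len(parts) != 3:
            raise TraceFormatError(f"{path}:{lineno}: expected 'index m_block rho_jack'")
        blocks.append(
            JackknifeBlock(index=int(parts[0]), m_block=int(parts[1]), rho_jack=float(parts[2]))
        )
    for key in ("VERSION", "NREF", "M", "B", "RHO", "SNP_DIGEST"):
        if key not in header:
            raise TraceFormatError(f"{path}: missing header line #{key}")
    if int(header["VERSION"]) != TRACE_VERSION:
        raise TraceFormatError(
            f"{path}: unsupported trace format version {header['VERSION']}"
        )
    summary = TraceSummary(
        n_ref=int(header["NREF"]),
        m=int(header["M"]),
        b_total=int(header["B"]),
        rho=float(header["RHO"]),
        blocks=blocks,
        digest=header["SNP_DIGEST"],
    )
    summary.validate()
    if snp_ids is not None:
        if snp_digest(snp_ids) != summary.digest:
            msg = f"{path}: SNP digest does not match the provided SNP list"
            if strict:
                raise TraceFormatError(msg)
            warnings.warn(msg)
        else:
            summary.snp_ids = list(snp_ids)
    return summary
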