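"""Simulation harness: architecture grids, calibration and accuracy metrics.

``run_grid`` simulates genotype panels and phenotype replicates over an
h2 x causal-ratio grid, runs the requested estimators on every replicate,
and aggregates bias / SE / MSE / false-positive-rate metrics per cell.
``relative_mse`` compares estimators cell-by-cell against a baseline with a
paired percentile bootstrap over replicate indices.

Two reference modes mirror how the summary-level estimator is deployed:

* ``in_sample``       -- the trace summary is computed on the same panel the
                         GWAS is run on;
* ``split_reference`` -- one simulated super-population is split into
                         disjoint reference and target samples; trace
                         summaries come only from the reference part, GWAS
                         and phenotypes only from the target part.

All randomness derives deterministically from the grid seed, so a
(grid, seed) pair reproduces the metrics table byte for byte.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from . import estimators as est
from .genotype_io import GenotypePanel, StandardizedGenotypes, standardize
from .gwas import run_gwas
from .phenosim import (
    ArchitectureConfig,
    MixtureConfig,
    draw_effects,
    simulate_genotypes,
    simulate_phenotype,
)
from .trace import TraceSummary, make_trace_summary, make_trace_summary_runs

ALL_ESTIMATORS = (est.METHOD_HE_EXACT, est.METHOD_RHE, est.METHOD_SUM_RHE)


@dataclasses.dataclass
class ExperimentGrid:
    """Full description of one simulation study."""

    h2_values: Sequence[float]
    causal_ratios: Sequence[float] = (1.0,)
    n_replicates: int = 100
    n: int = 2000
    m: int = 5000
    n_ref: int = 4000
    mixture: MixtureConfig | None = None
    seed: int = 0
    estimators: Sequence[str] = (est.METHOD_RHE, est.METHOD_SUM_RHE)
    reference_mode: str = "in_sample"  # or "split_reference"
    b: int = 100
    n_blocks: int = 100
    trace_runs: int = 25
    maf_low: float = 0.05
    maf_high: float = 0.5
    alpha: float = 0.05
    panel_scope: str = "cell"  # "grid" | "cell" | "replicate"

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.h2_values:
            raise ValueError("empty h2 grid")
        if self.reference_mode not in ("in_sample", "split_reference"):
            raise ValueError(f"unknown reference_mode {self.reference_mode!r}")
        if self.panel_scope not in ("grid", "cell", "replicate"):
            raise ValueError(f"unknown panel_scope {self.panel_scope!r}")
        unknown = set(self.estimators) - set(ALL_ESTIMATORS)
        if unknown:
            raise ValueError(f"unknown estimator(s) {sorted(unknown)}")

    def cells(self) -> list[tuple[float, float]]:
        ratios = (
            [self.mixture.alpha] if self.mixture is not None else list(self.causal_ratios)
        )
        if not ratios:
            raise ValueError("empty causal-ratio grid")
        return [(h2, p) for h2 in self.h2_values for p in ratios]


@dataclasses.dataclass
class MetricsTable:
    """Per-(cell, estimator) metrics plus the raw per-replicate estimates
    needed for paired bootstrap comparisons."""

    table: pd.DataFrame
    estimates: dict[tuple[float, float, str], np.ndarray]
    ses: dict[tuple[float, float, str], np.ndarray]
    failures: dict[tuple[float, float, str], int]
    grid: ExperimentGrid

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# grid: {self.grid}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(list(key))


def _subset_rows(panel: GenotypePanel, rows: slice) -> GenotypePanel:
    return GenotypePanel(
        samples=panel.samples[rows], snps=panel.snps, calls=panel.calls[rows]
    )


def _align(
    target: StandardizedGenotypes, ref: StandardizedGenotypes
) -> tuple[StandardizedGenotypes, StandardizedGenotypes]:
    """Restrict both standardized panels to their common SNPs (in target order).

    Needed only if in-sample filtering dropped different SNPs on the two
    sides of a reference/target split, which is rare at the MAFs simulated.
    """
    if target.snp_ids == ref.snp_ids:
        return target, ref
    common = [sid for sid in target.snp_ids if sid in set(ref.snp_ids)]
    return target.subset_snps(common), ref.subset_snps(common)


def _build_cell_data(grid: ExperimentGrid, cell_idx: int, cache: dict):
    """Panels and trace summaries for one grid cell, honoring panel_scope."""
    key = 0 if grid.panel_scope == "grid" else cell_idx + 1
    if key in cache:
        return cache[key]
    split = grid.reference_mode == "split_reference"
    n_total = grid.n + (grid.n_ref if split else 0)
    panel = simulate_genotypes(
        n_total, grid.m, grid.maf_low, grid.maf_high, seed=_rng(grid.seed, 101, key)
    )
    target_std = standardize(_subset_rows(panel, slice(0, grid.n)))
    if split:
        ref_std = standardize(_subset_rows(panel, slice(grid.n, n_total)))
        target_std, ref_std = _align(target_std, ref_std)
    else:
        ref_std = target_std

    sum_trace: TraceSummary | None = None
    exact_trace: TraceSummary | None = None
    if est.METHOD_SUM_RHE in grid.estimators:
        if grid.trace_runs > 1:
            sum_trace = make_trace_summary_runs(
                ref_std, b=grid.b, runs=grid.trace_runs, n_blocks=grid.n_blocks,
                seed=int(_rng(grid.seed, 102, key).integers(0, 2**31 - 1)),
            )
        else:
            sum_trace = make_trace_summary(
                ref_std, b=grid.b, n_blocks=grid.n_blocks, seed=_rng(grid.seed, 102, key)
            )
    if est.METHOD_HE_EXACT in grid.estimators:
        exact_trace = make_trace_summary(
            target_std, n_blocks=min(grid.n_blocks, target_std.m), exact=True
        )
    data = (target_std, sum_trace, exact_trace)
    cache[key] = data
    return data


def run_grid(grid: ExperimentGrid) -> MetricsTable:
    """Run every estimator on every replicate of every cell."""
    cache: dict = {}
    rows = []
    estimates: dict = {}
    ses: dict = {}
    failures: dict = {}

    for cell_idx, (h2, ratio) in enumerate(grid.cells()):
        if grid.panel_scope != "replicate":
            target_std, sum_trace, exact_trace = _build_cell_data(grid, cell_idx, cache)
        cfg = ArchitectureConfig(h2=h2, causal_ratio=ratio, mixture=grid.mixture)
        cell_est = {name: np.full(grid.n_replicates, np.nan) for name in grid.estimators}
        cell_se = {name: np.full(grid.n_replicates, np.nan) for name in grid.estimators}
        cell_fail = {name: 0 for name in grid.estimators}

        for r in range(grid.n_replicates):
            if grid.panel_scope == "replicate":
                cache.clear()
                target_std, sum_trace, exact_trace = _build_cell_data(
                    grid, cell_idx * grid.n_replicates + r, cache
                )
            effects = draw_effects(target_std.m, cfg, rng=_rng(grid.seed, 201, cell_idx, r))
            y = simulate_phenotype(
                target_std, effects, h2, seed=_rng(grid.seed, 202, cell_idx, r)
            )
            stats = (
                run_gwas(target_std, y)
                if est.METHOD_SUM_RHE in grid.estimators
                else None
            )
            for name in grid.estimators:
                try:
                    if name == est.METHOD_RHE:
                        fit = est.estimate_rhe(
                            target_std, y, b=grid.b, n_blocks=grid.n_blocks,
                            seed=_rng(grid.seed, 203, cell_idx, r),
                        )
                    elif name == est.METHOD_SUM_RHE:
                        fit = est.estimate_sumrhe(stats, sum_trace, n_target=grid.n)
                    else:
                        fit = est.estimate_he_exact(target_std, y, trace=exact_trace)
                except (est.EstimatorError, ValueError):
                    cell_fail[name] += 1
                    continue
                cell_est[name][r] = fit.h2
                cell_se[name][r] = fit.se

        for name in grid.estimators:
            vals = cell_est[name]
            ok = np.isfinite(vals)
            v = vals[ok]
            err = v - h2
            n_ok = int(ok.sum())
            emp_se = float(np.std(v, ddof=1)) if n_ok > 1 else np.nan
            rejections = [
                sval > 0 and hval / sval > _norm_isf(grid.alpha)
                for hval, sval in zip(vals[ok], cell_se[name][ok])
            ]
            rows.append(
                {
                    "h2": h2,
                    "causal_ratio": ratio,
                    "estimator": name,
                    "n_replicates": n_ok,
                    "n_failed": cell_fail[name],
                    "bias": float(err.mean()) if n_ok else np.nan,
                    "emp_se": emp_se,
                    "mean_jk_se": float(np.nanmean(cell_se[name][ok])) if n_ok else np.nan,
                    "mse": float((err**2).mean()) if n_ok else np.nan,
                    "fpr": float(np.mean(rejections)) if n_ok else np.nan,
                }
            )
            key = (h2, ratio, name)
            estimates[key] = vals
            ses[key] = cell_se[name]
            failures[key] = cell_fail[name]

    table = pd.DataFrame(rows)
    return MetricsTable(table=table, estimates=estimates, ses=ses, failures=failures, grid=grid)


def _norm_isf(alpha: float) -> float:
    from scipy import stats as sps

    return float(sps.norm.isf(alpha))


def relative_mse(
    mt: MetricsTable,
    baseline: str = est.METHOD_RHE,
    n_boot: int = 10_000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per-cell MSE of each estimator relative to ``baseline``, in percent,
    with a paired percentile-bootstrap confidence interval.

    Replicate indices are resampled once per bootstrap draw and applied to
    all estimators simultaneously, preserving the cross-estimator
    correlation induced by the shared phenotype replicates.
    """
    if baseline not in mt.grid.estimators:
        raise ValueError(f"baseline {baseline!r} not present in the metrics table")
    rng = np.random.default_rng([seed])
    lo_q = 100 * (1 - ci_level) / 2
    hi_q = 100 - lo_q
    out_rows = []
    for (h2, ratio) in mt.grid.cells():
        base = mt.estimates[(h2, ratio, baseline)]
        ok = np.isfinite(base)
        for name in mt.grid.estimators:
            ok &= np.isfinite(mt.estimates[(h2, ratio, name)])
        nrep = int(ok.sum())
        err_b = mt.estimates[(h2, ratio, baseline)][ok] - h2
        mse_b = float((err_b**2).mean())
        if mse_b == 0.0:
            raise ZeroDivisionError("baseline MSE is zero; relative MSE undefined")
        idx = rng.integers(0, nrep, size=(n_boot, nrep))
        den = (err_b**2)[idx].mean(axis=1)
        for name in mt.grid.estimators:
            if name == baseline:
                continue
            err_e = mt.estimates[(h2, ratio, name)][ok] - h2
            ratio_pct = 100.0 * float((err_e**2).mean()) / mse_b
            num = (err_e**2)[idx].mean(axis=1)
            boot = 100.0 * num / den
            out_rows.append(
                {
                    "h2": h2,
                    "causal_ratio": ratio,
                    "estimator": name,
                    "baseline": baseline,
                    "n_replicates": nrep,
                    "rel_mse": ratio_pct,
                    "rel_mse_ci_low": float(np.percentile(boot, lo_q)),
                    "rel_mse_ci_high": float(np.percentile(boot, hi_q)),
                }
            )
    return pd.DataFrame(out_rows)
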