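"""Marginal GWAS summary statistics and the adjusted z-score vector.

``run_gwas`` performs, per SNP, the simple OLS regression of a standardized
phenotype on the standardized dosage (centering makes this equivalent to
including an intercept).  ``adjusted_z`` rescales the per-SNP t-statistic to
z_j = (beta_j / se_j) * sqrt(N_j) / N, which for a standardized phenotype
reconstructs X'y / y'y from summary statistics alone -- the quantity the
summary-level heritability estimator consumes.

File interchange uses the PLINK 2 ``.glm.linear`` dialect (tab-separated,
header starting "#CHROM"; only ADD rows are consumed).
"""

from __future__ import annotations

import dataclasses
import io
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_io import StandardizedGenotypes

GLM_COLUMNS = [
    "#CHROM", "POS", "ID", "REF", "ALT", "A1", "TEST", "OBS_CT", "BETA", "SE", "T_STAT", "P",
]
REQUIRED_COLUMNS = ["ID", "OBS_CT", "BETA", "SE"]


class SumstatsFormatError(ValueError):
    """Summary-statistics file does not conform to the expected dialect."""


@dataclasses.dataclass
class GwasSumstats:
    ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    obs_ct: np.ndarray
    n_total: int
    chrom: list[str] | None = None
    pos: np.ndarray | None = None

    @property
    def m(self) -> int:
        return len(self.ids)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=np.float64)
        self.se = np.asarray(self.se, dtype=np.float64)
        self.obs_ct = np.asarray(self.obs_ct, dtype=np.int64)
        if not (self.beta.size == self.se.size == self.obs_ct.size == len(self.ids)):
            raise ValueError("per-SNP fields must have equal length")


@dataclasses.dataclass
class AdjustedZVector:
    z: np.ndarray
    m: int
    n: int


def run_gwas(
    geno: StandardizedGenotypes,
    y: np.ndarray,
    approx_se: bool = False,
) -> GwasSumstats:
    """Per-SNP simple OLS of y on each standardized dosage column.

    ``approx_se`` replaces the exact residual-based standard error with the
    large-sample approximation s_j = sqrt(y'y / (N * N_j)); this is the SE
    convention under which the summary-level estimator reproduces the
    individual-level method-of-moments estimate exactly.
    """
    y = np.asarray(y, dtype=np.float64)
    x = geno.matrix
    n = x.shape[0]
    if y.size != n:
        raise ValueError(f"phenotype length {y.size} != sample count {n}")
    yy = float(y @ y)
    if abs(yy / n - 1.0) > 1e-6:
        raise ValueError("phenotype must be standardized (y'y = N); see standardize_phenotype")

    xty = x.T @ y
    xtx = np.einsum("ij,ij->j", x, x)  # = N per column under divisor-N scaling
    beta = xty / xtx
    obs = geno.obs_counts.astype(np.int64)
    if approx_se:
        se = np.sqrt(yy / (n * obs))
    else:
        rss = yy - beta * xty
        if np.any(rss < -1e-8 * yy):
            raise ValueError("negative residual sum of squares; inconsistent inputs")
        rss = np.clip(rss, 0.0, None)
        if np.any(rss == 0.0):
            warnings.warn("perfect fit for some SNP(s); SE is degenerate (0)")
        df = obs - 2
        if np.any(df <= 0):
            raise ValueError("need more than 2 observed calls per SNP for exact SEs")
        se = np.sqrt(rss / df / xtx)
    return GwasSumstats(
        ids=list(geno.snp_ids), beta=beta, se=se, obs_ct=obs, n_total=n,
    )


def adjusted_z(stats: GwasSumstats, n_total: int | None = None) -> AdjustedZVector:
    """z_j = (beta_j / se_j) * sqrt(N_j) / N."""
    n = int(n_total) if n_total is not None else int(stats.n_total)
    if n <= 0:
        raise ValueError("n_total must be positive")
    bad = np.nonzero(stats.se <= 0.0)[0]
    if bad.size:
        raise ValueError(f"non-positive SE for SNP(s) {[stats.ids[j] for j in bad[:5]]}")
    z = stats.beta / stats.se * np.sqrt(stats.obs_ct) / n
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite adjusted z-scores")
    return AdjustedZVector(z=z, m=stats.m, n=n)


def write_sumstats(stats: GwasSumstats, path: str | Path) -> None:
    """Write the PLINK 2 ``.glm.linear`` dialect (ADD rows only)."""
    chrom = stats.chrom if stats.chrom is not None else ["1"] * stats.m
    pos = stats.pos if stats.pos is not None else np.arange(1, stats.m + 1)
    with Path(path).open("w") as fh:
        fh.write("\t".join(GLM_COLUMNS) + "\n")
        for j in range(stats.m):
            b, s = stats.beta[j], stats.se[j]
            t = b / s if s > 0 else np.nan
            p = 2.0 * sps.norm.sf(abs(t)) if np.isfinite(t) else np.nan
            fh.write(
                f"{chrom[j]}\t{pos[j]}\t{stats.ids[j]}\tG\tA\tA\tADD\t"
                f"{stats.obs_ct[j]}\t{b:.17g}\t{s:.17g}\t{t:.17g}\t{p:.17g}\n"
            )


def read_sumstats(path: str | Path, n_total: int | None = None) -> GwasSumstats:
    """Read a ``.glm.linear``-style table.

    Requires a header line beginning ``#CHROM`` with at least the columns
    ID, OBS_CT, BETA and SE; extra columns are ignored and only TEST == ADD
    rows (when a TEST column exists) are consumed.  ``n_total`` defaults to
    max(OBS_CT).
    """
    path = Path(path)
    text = path.read_text()
    first = text.splitlines()[0] if text else ""
    if not first.startswith("#CHROM"):
        raise SumstatsFormatError(f"{path}: header must begin with '#CHROM'")
    df = pd.read_csv(io.StringIO(text), sep=r"\s+", float_precision="round_trip")
    df.columns = [c if c != "#CHROM" else "#CHROM" for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SumstatsFormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    if "TEST" in df.columns:
        df = df[df["TEST"] == "ADD"]
    for col in ("OBS_CT", "BETA", "SE"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SumstatsFormatError(
                f"{path}: non-numeric {col} at data row {int(bad[0]) + 2}"
            )
        if coerced.isna().any():
            raise SumstatsFormatError(f"{path}: missing {col} value")
        df[col] = coerced
    n = int(n_total) if n_total is not None else int(df["OBS_CT"].max())
    return GwasSumstats(
        ids=[str(v) for v in df["ID"]],
        beta=df["BETA"].to_numpy(dtype=np.float64),
        se=df["SE"].to_numpy(dtype=np.float64),
        obs_ct=df["OBS_CT"].to_numpy(dtype=np.int64),
        n_total=n,
        chrom=[str(v) for v in df["#CHROM"]] if "#CHROM" in df.columns else None,
        pos=df["POS"].to_numpy() if "POS" in df.columns else None,
    )
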