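"""Synthetic genotype panels and polygenic phenotypes.

Phenotypes follow the additive model y = X beta + eps, where X is the
column-standardized genotype matrix, the effect sizes beta are drawn from a
sparse (spike-and-slab) or large/small-effect mixture architecture, and eps
is i.i.d. Gaussian noise with variance 1 - h2.  Effect variances are chosen
so the *expected* total genetic variance equals the target SNP heritability
h2 regardless of the causal ratio; realized heritability then fluctuates
around h2, which keeps estimator-bias experiments honest (an opt-in flag
rescales to the exact target instead).

Genotypes are unlinked biallelic SNPs by default (per-SNP MAF drawn
uniformly, calls Binomial(2, maf)); a block-correlated generator based on a
thresholded AR(1) latent Gaussian is available to exercise LD-dependent
behavior of the trace machinery.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .genotype_io import GenotypePanel, SnpRecord, StandardizedGenotypes


def _coerce_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclasses.dataclass(frozen=True)
class MixtureConfig:
    """Large/small effect mixture: the first ``pi`` fraction of SNPs carries a
    ``gamma`` share of h2; within each group SNPs are causal with probability
    ``alpha``."""

    pi: float
    gamma: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.pi < 1.0:
            raise ValueError("pi must be in (0, 1)")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")


@dataclasses.dataclass(frozen=True)
class ArchitectureConfig:
    """Target h2 plus the sparsity/mixture description of the effect sizes."""

    h2: float
    causal_ratio: float = 1.0
    mixture: MixtureConfig | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        if not 0.0 < self.causal_ratio <= 1.0:
            raise ValueError("causal_ratio must be in (0, 1]")


@dataclasses.dataclass
class EffectVector:
    beta: np.ndarray
    causal_idx: np.ndarray

    @property
    def n_causal(self) -> int:
        return self.causal_idx.size


def simulate_genotypes(
    n: int,
    m: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    seed=None,
) -> GenotypePanel:
    """Unlinked biallelic SNPs: MAF ~ Uniform(maf_low, maf_high), calls
    Binomial(2, maf) independently per sample."""
    if n < 2 or m < 1:
        raise ValueError("need n >= 2 samples and m >= 1 SNPs")
    if not 0.0 < maf_low <= maf_high <= 0.5:
        raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
    rng = _coerce_rng(seed)
    mafs = rng.uniform(maf_low, maf_high, size=m)
    calls = rng.binomial(2, mafs, size=(n, m)).astype(np.int8)
    return GenotypePanel(
        samples=[(f"F{i + 1}", f"I{i + 1}") for i in range(n)],
        snps=_default_snps(m),
        calls=calls,
    )


def simulate_genotypes_ld(
    n: int,
    m: int,
    block_size: int = 50,
    r: float = 0.5,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    seed=None,
) -> GenotypePanel:
    """Block-correlated SNPs via a thresholded AR(1) latent Gaussian.

    Haplotypes within a block share an AR(1) latent process with lag-one
    correlation ``r``; each haplotype carries the minor allele when its
    latent value falls below the MAF quantile.  The realized genotype
    correlation is below ``r`` (dichotomization attenuates), which is fine:
    the generator exists to produce *some* LD, not a calibrated amount.
    """
    if not 0.0 <= r < 1.0:
        raise ValueError("r must be in [0, 1)")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    rng = _coerce_rng(seed)
    mafs = rng.uniform(maf_low, maf_high, size=m)
    thresh = stats.norm.ppf(mafs)
    calls = np.zeros((n, m), dtype=np.int8)
    carry = np.sqrt(1.0 - r * r)
    for _hap in range(2):
        eps = rng.standard_normal((n, m))
        latent = np.empty((n, m))
        for j in range(m):
            if j % block_size == 0:
                latent[:, j] = eps[:, j]
            else:
                latent[:, j] = r * latent[:, j - 1] + carry * eps[:, j]
        calls += (latent < thresh[None, :]).astype(np.int8)
    return GenotypePanel(
        samples=[(f"F{i + 1}", f"I{i + 1}") for i in range(n)],
        snps=_default_snps(m),
        calls=calls,
    )


def _default_snps(m: int) -> list[SnpRecord]:
    width = len(str(m))
    return [
        SnpRecord(chrom="1", id=f"snp{j + 1:0{width}d}", pos=j + 1, a1="A", a2="G")
        for j in range(m)
    ]


def _causal_variances(m: int, cfg: ArchitectureConfig) -> tuple[float, float]:
    """Per-causal-SNP effect variances (large group, small group).

    Baseline architectures use a single value h2/(M*P) for both slots.
    """
    if cfg.mixture is None:
        v = cfg.h2 / (m * cfg.causal_ratio)
        return v, v
    mix = cfg.mixture
    v_large = mix.gamma * cfg.h2 / (mix.pi * m * mix.alpha)
    v_small = (1.0 - mix.gamma) * cfg.h2 / ((1.0 - mix.pi) * m * mix.alpha)
    return v_large, v_small


def draw_effects(m: int, cfg: ArchitectureConfig, rng=None) -> EffectVector:
    """Draw standardized per-SNP effect sizes under ``cfg``.

    If the causal mask comes up empty while h2 > 0 (possible when P*M is
    tiny) the mask is redrawn, so a non-null architecture never yields a
    null phenotype.
    """
    rng = _coerce_rng(cfg.seed if rng is None else rng)
    if cfg.mixture is not None and cfg.mixture.pi * m < 1:
        raise ValueError("mixture requires pi * m >= 1")

    beta = np.zeros(m)
    if cfg.h2 == 0.0:
        return EffectVector(beta=beta, causal_idx=np.array([], dtype=np.intp))

    v_large, v_small = _causal_variances(m, cfg)
    if cfg.mixture is None:
        p_causal = np.full(m, cfg.causal_ratio)
        sd = np.full(m, np.sqrt(v_large))
    else:
        m_large = int(np.floor(cfg.mixture.pi * m))
        p_causal = np.full(m, cfg.mixture.alpha)
        sd = np.where(np.arange(m) < m_large, np.sqrt(v_large), np.sqrt(v_small))

    for _attempt in range(1000):
        mask = rng.random(m) < p_causal
        if mask.any():
            break
    else:  # pragma: no cover - astronomically unlikely with sane configs
        raise RuntimeError("failed to draw a non-empty causal set")

    idx = np.nonzero(mask)[0]
    beta[idx] = rng.normal(0.0, sd[idx])
    return EffectVector(beta=beta, causal_idx=idx)


def standardize_phenotype(y: np.ndarray) -> np.ndarray:
    """Center and scale so that mean(y) = 0 and y'y = N (divisor-N variance 1)."""
    y = np.asarray(y, dtype=np.float64)
    y = y - y.mean()
    ss = float(y @ y) / y.size
    if ss <= 0.0:
        raise ValueError("phenotype has zero variance; cannot standardize")
    return y / np.sqrt(ss)


def simulate_phenotype(
    geno: StandardizedGenotypes | np.ndarray,
    effects: EffectVector,
    h2: float,
    seed=None,
    exact_h2: bool = False,
) -> np.ndarray:
    """y = X beta + eps with Var(eps) = 1 - h2, returned re-standardized to
    mean 0 and y'y = N.

    With ``exact_h2`` the genetic and noise parts are rescaled so the
    realized variance split matches h2 exactly (before the final
    re-standardization); by default the realized split fluctuates around the
    target.
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must be in [0, 1]")
    x = geno.matrix if isinstance(geno, StandardizedGenotypes) else np.asarray(geno)
    rng = _coerce_rng(seed)
    n = x.shape[0]
    g = x @ effects.beta
    eps = rng.standard_normal(n) * np.sqrt(1.0 - h2)
    if exact_h2:
        if h2 > 0.0:
            gss = float(g @ g) / n
            if gss <= 0.0:
                raise ValueError("exact_h2 requires a nonzero genetic component")
            g = g * np.sqrt(h2 / gss)
        else:
            g = np.zeros(n)
        if h2 < 1.0:
            ess = float(eps @ eps) / n
            eps = eps * np.sqrt((1.0 - h2) / ess)
        else:
            eps = np.zeros(n)
    y = g + eps
    return standardize_phenotype(y)
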