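"""PLINK 1 binary genotype I/O and column standardization.

Genotypes are held as counted-allele (A1) dosages in {0, 1, 2}, with ``-1``
marking a missing call.  ``standardize`` converts a raw panel into the
column-standardized matrix X used throughout the heritability estimators:
each SNP column is mean-centered and scaled so that its sum of squares
equals the sample count N exactly (population-variance divisor).  Under this
convention the genetic relatedness matrix K = XX'/M satisfies tr(K) = N,
which the method-of-moments normal equations rely on.

Missing calls are mean-imputed before centering, so they contribute exactly
zero to every inner product afterwards; per-SNP observed-call counts are
retained for GWAS OBS_CT reporting.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

MISSING = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_MODE_SNP_MAJOR = 0x01
# 2-bit code (low-to-high within byte) -> A1 dosage
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
# dosage (indexed as dosage + 1, so MISSING=-1 maps to slot 0) -> 2-bit code
_BED_ENCODE = np.array([1, 3, 2, 0], dtype=np.uint8)


class PlinkFormatError(ValueError):
    """Malformed or inconsistent PLINK 1 fileset."""


class EmptyPanelError(ValueError):
    """No SNPs survive filtering."""


@dataclasses.dataclass(frozen=True)
class SnpRecord:
    """One .bim row: chromosome, identifier, position and alleles."""

    chrom: str
    id: str
    pos: int
    a1: str
    a2: str
    cm: float = 0.0


@dataclasses.dataclass
class GenotypePanel:
    """Raw allele-count matrix plus sample/SNP metadata.

    ``calls`` is an N x M int8 matrix with entries in {0, 1, 2, MISSING}.
    """

    samples: list[tuple[str, str]]
    snps: list[SnpRecord]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, m = self.calls.shape
        if n != len(self.samples) or m != len(self.snps):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be 0, 1, 2 or the missing sentinel")
        ids = [s.id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids in panel")

    @property
    def n(self) -> int:
        return self.calls.shape[0]

    @property
    def m(self) -> int:
        return self.calls.shape[1]


@dataclasses.dataclass
class StandardizedGenotypes:
    """Column-standardized genotype matrix X.

    Every column has mean 0 and sum of squares N (divisor-N variance 1), so
    x_j'x_j = N and tr(XX'/M) = N hold exactly.  ``freqs`` holds the
    counted-allele frequency of each retained SNP, ``obs_counts`` the number
    of non-missing calls, and ``dropped`` the ids removed as monomorphic or
    all-missing.
    """

    matrix: np.ndarray
    snp_ids: list[str]
    freqs: np.ndarray
    obs_counts: np.ndarray
    dropped: list[str] = dataclasses.field(default_factory=list)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def m(self) -> int:
        return self.matrix.shape[1]

    def subset_snps(self, keep_ids: list[str]) -> "StandardizedGenotypes":
        """Restrict to ``keep_ids`` (in the given order); columns stay standardized."""
        pos = {sid: j for j, sid in enumerate(self.snp_ids)}
        idx = np.array([pos[sid] for sid in keep_ids], dtype=np.intp)
        return StandardizedGenotypes(
            matrix=self.matrix[:, idx],
            snp_ids=list(keep_ids),
            freqs=self.freqs[idx],
            obs_counts=self.obs_counts[idx],
            dropped=list(self.dropped),
        )


def read_plink(prefix: str | Path) -> GenotypePanel:
    """Read a PLINK 1 ``.bed``/``.bim``/``.fam`` triplet (SNP-major only)."""
    prefix = Path(prefix)
    fam_path = prefix.with_suffix(".fam")
    bim_path = prefix.with_suffix(".bim")
    bed_path = prefix.with_suffix(".bed")

    samples = []
    for line in fam_path.read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        samples.append((parts[0], parts[1]))

    snps = []
    for line in bim_path.read_text().splitlines():
        if not line.strip():
            continue
        chrom, sid, cm, pos, a1, a2 = line.split()[:6]
        snps.append(SnpRecord(chrom=chrom, id=sid, pos=int(pos), a1=a1, a2=a2, cm=float(cm)))

    raw = bed_path.read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes (not a PLINK 1 .bed file)")
    if raw[2] != _BED_MODE_SNP_MAJOR:
        raise PlinkFormatError(
            f"{bed_path}: mode byte {raw[2]:#04x} unsupported (only SNP-major 0x01)"
        )
    n, m = len(samples), len(snps)
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{bed_path}: size mismatch, expected {expected} bytes "
            f"(3 + ceil({n}/4) x {m}) but found {len(raw)}"
        )

    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # expand each byte into four 2-bit codes, low bits first
    codes = (data[:, :, None] >> np.array([0, 2, 4, 6], dtype=np.uint8)) & 3
    codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
    calls = _BED_DECODE[codes].T  # N x M

    return GenotypePanel(samples=samples, snps=snps, calls=calls)


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write a panel as a PLINK 1 ``.bed``/``.bim``/``.fam`` triplet."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    with prefix.with_suffix(".fam").open("w") as fh:
        for fid, iid in panel.samples:
            fh.write(f"{fid} {iid} 0 0 0 -9\n")
    with prefix.with_suffix(".bim").open("w") as fh:
        for s in panel.snps:
            fh.write(f"{s.chrom}\t{s.id}\t{s.cm:g}\t{s.pos}\t{s.a1}\t{s.a2}\n")

    n, m = panel.n, panel.m
    bytes_per_snp = (n + 3) // 4
    codes = _BED_ENCODE[panel.calls.T.astype(np.int16) + 1]  # M x N uint8
    padded = np.ones((m, bytes_per_snp * 4), dtype=np.uint8)  # pad code 01 is ignored on read
    padded[:, :n] = codes
    padded = padded.reshape(m, bytes_per_snp, 4)
    packed = (
        padded[:, :, 0]
        | (padded[:, :, 1] << 2)
        | (padded[:, :, 2] << 4)
        | (padded[:, :, 3] << 6)
    ).astype(np.uint8)
    with prefix.with_suffix(".bed").open("wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(bytes([_BED_MODE_SNP_MAJOR]))
        fh.write(packed.tobytes())


def standardize(panel: GenotypePanel, maf_min: float = 0.0) -> StandardizedGenotypes:
    """Standardize a panel: drop monomorphic/all-missing SNPs, mean-impute,
    center and scale each column to sum-of-squares N.

    ``maf_min`` optionally drops SNPs whose minor-allele frequency is below
    the threshold (a plain frequency filter, not part of the estimator).
    """
    if panel.n < 2:
        raise ValueError("standardize requires at least 2 samples")
    calls = panel.calls
    n = panel.n
    observed = calls != MISSING
    obs_counts = observed.sum(axis=0)
    vals = np.where(observed, calls, 0).astype(np.int64)
    s1 = vals.sum(axis=0)
    s2 = (vals * vals).sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = s1 / (2.0 * obs_counts)
    # integer identity: observed variance is zero iff n_obs * sum(x^2) == (sum x)^2
    degenerate = (obs_counts == 0) | (obs_counts * s2 == s1 * s1)
    keep = ~degenerate
    if maf_min > 0.0:
        maf = np.minimum(freqs, 1.0 - freqs)
        keep &= maf >= maf_min

    dropped = [panel.snps[j].id for j in np.nonzero(~keep)[0]]
    if not keep.any():
        raise EmptyPanelError("no SNPs survive standardization filtering")

    idx = np.nonzero(keep)[0]
    x = calls[:, idx].astype(np.float64)
    col_obs = observed[:, idx]
    means = s1[idx] / obs_counts[idx]
    x = np.where(col_obs, x, means[None, :])
    x -= means[None, :]
    # divisor-N scale over the full (imputed) column -> x'x = N exactly
    sd = np.sqrt((x * x).sum(axis=0) / n)
    x /= sd[None, :]

    return StandardizedGenotypes(
        matrix=x,
        snp_ids=[panel.snps[j].id for j in idx],
        freqs=freqs[idx],
        obs_counts=obs_counts[idx],
        dropped=dropped,
    )


def read_pheno(path: str | Path) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Read a whitespace FID IID PHENO table (optional header, NA allowed).

    Returns the sample ids and a float vector with NaN for missing values.
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty phenotype file")
    first = lines[0].split()
    has_header = first[0].lstrip("#").upper() == "FID"
    body = lines[1:] if has_header else lines
    samples, values = [], []
    for lineno, line in enumerate(body, start=2 if has_header else 1):
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected FID IID PHENO")
        samples.append((parts[0], parts[1]))
        values.append(np.nan if parts[2].upper() in ("NA", "NAN") else float(parts[2]))
    return samples, np.array(values, dtype=np.float64)


def write_pheno(path: str | Path, samples: list[tuple[str, str]], y: np.ndarray) -> None:
    with Path(path).open("w") as fh:
        fh.write("FID IID PHENO\n")
        for (fid, iid), val in zip(samples, y):
            fh.write(f"{fid} {iid} {'NA' if np.isnan(val) else format(val, '.17g')}\n")
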