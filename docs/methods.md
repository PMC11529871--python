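# Methods

## Model

Phenotypes follow the standard additive linear mixed model. With a
column-standardized genotype matrix **X** (N individuals × M SNPs) and a
standardized phenotype **y** (mean 0, y'y = N),

    y = Xβ + ε,   β ~ D(0, (σ_g²/M)·I_M),   ε ~ D(0, σ_e²·I_N),

where D is an arbitrary mean-zero distribution. SNP heritability is
h² = σ_g²/(σ_g² + σ_e²). The method-of-moments (Haseman–Elston) estimator
matches the sample covariance yy' to the population covariance
σ_g²·K + σ_e²·I, where K = XX'/M is the genetic relatedness matrix. Solving
the resulting 2×2 normal equations gives

    σ̂_g² = (y'Ky − y'y) / (tr(K²) − N),   σ̂_e² = y'y/N − σ̂_g²,

and, because y is standardized, ĥ² = σ̂_g². No distributional assumption on
β or ε enters, which is why the estimator stays unbiased across sparse and
mixture architectures.

## The three estimators

All three are the same normal-equation solve; they differ only in where the
two data-dependent quantities come from.

* **HE_EXACT** computes y'Ky = ‖X'y‖²/M and tr(K²) = ‖X'X‖_F²/M² exactly.
  The Gram route costs O(M²N) and is the small-panel oracle.
* **RHE** replaces tr(K²) with the Hutchinson stochastic estimate
  (1/B)·Σ_b ‖X(X'z_b)‖²/M² using B standard-normal probe vectors z_b
  (E[z z'] = I makes the quadratic form unbiased for the trace). Cost
  O(MNB); B = 100 is the default, which is accurate at the sample sizes
  used here. Rademacher probes are available behind a flag but are not the
  default.
* **SUM_RHE** reconstructs the estimate from summary data alone. The
  adjusted z-score z_j = (β̂_j/s_j)·√N_j/N reconstructs X'y/y'y from GWAS
  output, because β̂_j = x_j'y/N for standardized dosages and the
  large-sample SE is s_j ≈ sqrt(y'y/(N·N_j)). Since N·z'z/M = y'Ky/y'y and
  the *trace summary* ρ̂ = (tr(K²)/N − 1)/N satisfies N·ρ̂ = tr(K²)/N − 1,

      ĥ² = (N·z'z/M − 1) / (N·ρ̂).

  With an in-sample exact trace and the approximate-SE convention this is
  algebraically identical to HE_EXACT (the test suite asserts equality to
  1e-8); with real OLS standard errors the two differ by O(1/N).

ρ̂ is, up to O(1/N) terms, the mean population LD score over SNPs divided by
M (for unlinked SNPs tr(K²) ≈ N + N²/M, so ρ̂ ≈ 1/M). It is a property of
the population's LD, not of the phenotype or of the particular sample, which
is what makes it transferable: a reference cohort can compute and release ρ̂
with its jackknife replicates (a few KB of text), and any GWAS on the same
population can then estimate h² without individual data.

## Standardization conventions

Genotype columns are mean-centered and scaled so the column sum of squares
equals N exactly (population-variance divisor). This makes tr(K) = N and
x_j'x_j = N identities rather than approximations, which the normal
equations above assume. Missing calls are mean-imputed before centering
(imputed entries become exactly 0 and drop out of every inner product);
per-SNP observed counts are kept for OBS_CT. Monomorphic and all-missing
SNPs are dropped with a report, never an error, because small simulated
panels produce them. Allele orientation is the stored A1 dosage; every
downstream quantity is a square or quadratic form, so a global sign flip of
a column is irrelevant (property-tested). Phenotypes are standardized with
the same divisor-N convention.

## Jackknife standard errors

SEs come from a leave-one-SNP-block-out jackknife: contiguous blocks of
floor(M/n_blocks) SNPs (remainder appended to the last block; 100 blocks by
default at desk scale). For each left-out block both the numerator
(‖X'y‖² or z'z) and the trace are recomputed with M_jack = M − m_block
renormalization; trace summaries ship one ρ̂_jack per block so summary-level
users can form the same replicates. The stochastic leave-one-out values
reuse the full run's probe vectors and equal a physical subset computation
exactly (tested to 1e-8). The SE is

    SE = sqrt( (n−1)/n · Σ_i (ĥ²_i − mean(ĥ²_·))² ),

the standard delete-one block jackknife. Estimates are never clamped to
[0, 1]; under a true null about half of them are negative, and the
one-sided test p = 1 − Φ(ĥ²/SE) at α = 0.05 holds its level only because of
that (a presentation-only clamp flag exists in the CLI).

## Trace-summary aggregation

Stochastic trace runs average linearly, and ρ̂ is affine in the trace, so
aggregating R runs of B probes by B-weighted means equals one run with R·B
probes in expectation. The default protocol for building a released trace
summary is 25 runs × B = 100 (an effective B′ = 2500), aggregated with
`aggregate_trace_runs`; per-run probe seeds derive deterministically from
one master seed.

## Synthetic data

The generator is the study design, not a convenience:

* Genotypes: M unlinked biallelic SNPs, per-SNP MAF ~ Uniform(0.05, 0.5),
  calls Binomial(2, maf). An optional AR(1)-latent-threshold generator adds
  block LD to exercise the trace machinery; its realized genotype
  correlation is attenuated relative to the latent parameter and is not
  calibrated.
* Effects: each SNP causal independently with probability P (the causal
  ratio); causal effects N(0, h²/(M·P)), so the expected total genetic
  variance is h² for every P. The mixture model assigns the first
  floor(π·M) SNPs to a large-effect group carrying a γ share of h²:
  causal variances γh²/(πMα) and (1−γ)h²/((1−π)Mα) with a single shared
  within-group causal probability α (the natural reading where the two
  groups differ in variance, not in causal density). With γ = π the mixture
  collapses to the baseline model, which is property-tested. If a sparse
  draw yields zero causal SNPs while h² > 0, the mask is redrawn, so a
  non-null configuration never produces a null phenotype.
* Phenotypes: y = Xβ + ε with ε ~ N(0, 1−h²), then re-standardized. By
  default β is *not* rescaled to pin the realized genetic variance at h²
  (rescaling would understate estimator dispersion); an `exact_h2` flag
  provides the pinned variant.

What this generator does not emulate: realistic LD (beyond the optional
toy blocks), MAF- or LD-dependent effect coupling, covariates, population
stratification, relatedness, case/control liability. Passing tests
therefore demonstrate correctness of the estimator under its own model
assumptions and transferability of ρ̂ within a homogeneous population —
not robustness to confounded or structured real data, which the method
itself (like any summary-statistics approach without an intercept term)
does not claim.

## Experiment harness and problem sizes

`run_grid` runs an h² × causal-ratio grid with a configurable number of
phenotype replicates per cell. Genotype panels are reused across replicates
within a cell (fresh phenotypes per replicate); `panel_scope` selects one
panel per cell (default), one shared panel for the whole grid (used by the
relative-MSE study, which compares estimators on identical data), or fresh
panels per replicate. In `split_reference` mode one simulated
super-population is split into disjoint reference and target samples; trace
summaries come only from the reference half. RHE draws fresh probe vectors
on every replicate — each replicate is one independent invocation of the
individual-level tool — while the SUM-RHE trace summary is a single fixed
artifact per panel, exactly as it would be released in practice.

Desk-scale defaults are N = 2000 target (4000 reference in split mode),
M = 5000 SNPs, B = 100 probes, 100 jackknife blocks and 100 replicates per
cell, chosen so a full 3×3 grid completes in a few minutes on one core
while keeping N/M in a regime where the estimator's variance is dominated
by the same terms as at biobank scale. Relative-MSE comparisons use a
paired percentile bootstrap (10 000 resamples by default) that resamples
replicate indices jointly across estimators, preserving the correlation
induced by shared phenotypes; resampling replicates and resampling squared
errors are equivalent for the ratio-of-MSE statistic. The mixture-model
recovery experiments use π = 0.05, γ = 0.25, α ∈ {1.0, 0.1} at h² = 0.25
(a middle value; the mixture design does not pin a specific h²).

## Numerical choices and degenerate inputs

* All quadratic forms accumulate in float64 regardless of input storage.
* ρ̂ ≤ 0 (possible with tiny B on tiny panels, since tr(K²) > N is only
  guaranteed in expectation) is a hard error in every estimator — a sign
  flip would invert the estimate — as is tr(K²) = N in exact mode.
* A perfect per-SNP fit in the GWAS (RSS = 0) yields SE = 0 with a warning;
  the adjusted-z computation then refuses the SNP by name.
* Trace files round-trip at 17 significant digits (bit-exact for float64);
  SNP-set identity between sumstats and trace is enforced via an
  order-sensitive SHA-256 digest of the id list, with an explicit
  `intersect` escape hatch that loudly warns that the released ρ̂ values
  then refer to a superset panel.
* `n_target` precedence in the summary estimator: explicit argument, then
  the sumstats' recorded N, then max(OBS_CT) at file read.

## Known limitations

Two desk-scale artifacts concentrate in the sparsest, highest-h² corner of
the simulation grid (h² = 0.4, causal ratio 0.01, i.e. ~50 causal SNPs on a
5000-SNP panel); both shrink as the inverse causal count and are negligible
at biobank-scale panels.

First, summary-statistics estimates consume exact OLS standard errors (what
GWAS tools actually emit), and the resulting t² = (N−2)r²/(1−r²) exceeds
the N·r² of the exact algebraic reconstruction by a term of order Σ_j r_j⁴.
With very few causal SNPs that term is material (~+0.01 on ĥ² in that
corner cell, raising the MSE relative to individual-level RHE by a few
percent); with thousands of causal SNPs it is invisible.

Second, at desk scale the SNP-block jackknife is conservative for extremely sparse
architectures: with only tens of causal SNPs on a 5000-SNP panel, per-block
signal shares are heavy-tailed and the jackknife counts that heterogeneity
as sampling noise, overstating the SE by up to about a third at
h² = 0.4, P = 0.01 (the validation suite measures this). The effect scales
as the inverse causal count per panel and is negligible at
biobank-scale SNP panels, where the same protocol is well calibrated.

Single-component estimates only (no MAF/LD-stratified or partitioned
heritability, which would require partitioned trace summaries); no
confounding correction — summary statistics are assumed free of
stratification and relatedness; no dosage/VCF input (PLINK 1 binary only);
the exact-trace oracle is quadratic in M and intended for panels up to a
few thousand SNPs.
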