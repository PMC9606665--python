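# Methods

## Model and estimation

The statistical model throughout is the single-trait animal model
`y = 1μ + Zu + e`, `u ~ N(0, K σ²g)`, `e ~ N(0, I σ²e)`, with the overall
mean as the only fixed effect. Breeding values are obtained by solving the
mixed model equations directly (dense solve; the systems of interest have at
most a few thousand equations). Individuals without phenotypes remain in the
equations, so their EBVs are propagated through K⁻¹ — the single-step usage.

### REML

For one random effect the marginal covariance of the phenotyped subset is
`V = σ²g (K_obs + λI)` with `λ = σ²e/σ²g`, so the restricted likelihood is a
smooth function of the single ratio once σ²g and μ are profiled out. The
implementation eigendecomposes `K_obs` once, rotates `y` and the intercept
column, and maximizes the profiled restricted log-likelihood over `log₁₀ λ`
by locating the zero crossing of its analytic gradient (coarse sign scan
over `log₁₀ λ ∈ [−6, 6]`, then Brent root-finding, `xtol` 1e−12). A
derivative-free minimization was deliberately not used: locating a minimum
from function values alone is limited to roughly square-root machine
precision in the parameter, which is not enough for the exact-identity
checks below; the gradient root is found to ~1e−12, and the closed-form
responses to rescaling (σ̂²g(wK) = σ̂²g/w with ĥ² = 1/(1+wλ₀);
σ̂²g(wK⁻¹) = w·σ̂²g with ĥ² = w/(w+λ₀)) then hold to ~1e−12 rather than
~1e−8. An EM iteration would reach the same stationary point, only less
reliably near flat likelihoods. A monotone gradient over the whole scan
range means the optimum sits at a parameter boundary (h² → 0 or → 1); the
estimate is clamped there with a warning and flagged as non-converged.
`K_obs` must be positive semi-definite (eigenvalues below −1e−8 relative
raise a singularity error; small negative rounding is clipped).

The reported log-likelihood is the REML log-likelihood up to an additive
constant. Tests cross-check the estimator against an independent brute-force
route: Nelder-Mead on the explicit `−2·restricted log-likelihood` computed
from dense `V` determinants and inverses.

### Matrix construction

- **A** (tabular): row i is the half-sum of the parents' rows,
  `A_ii = 1 + a(s,d)/2`. Inbreeding coefficients are the diagonal minus one.
  The recursion is exact; no approximation is used at any pedigree size this
  package targets (thousands of individuals).
- **A⁻¹** (Henderson's rules): per-trio contributions `1/d_i` with
  Mendelian-sampling variance `d_i = 0.5 − 0.25(F_s + F_d)` (both parents),
  `0.75 − 0.25 F_p` (one parent), `1` (founder). With inbreeding accounted
  (the default) the construction equals the dense inverse of the tabular A
  exactly; `use_inbreeding=False` reproduces the classical biased shortcut
  for comparison.
- **G** (VanRaden method 1): `G = WW′ / (2Σ pₗ(1−pₗ))`, W the column-centred
  −1/0/+1 coding (`M − 2p + 1`). Dosage 0/1/2 maps to −1/0/+1; fully inbred
  0/1 lines map to −1/+1. Allele frequencies default to the observed
  frequencies of the input genotypes, as with real data where base
  frequencies are unknown; a fixed-frequency override exists and is the
  right choice when comparing G against pedigree expectations (A is defined
  relative to the founders). Markers with minor allele frequency below 0.02
  are dropped before construction.
- **H⁻¹**: `A⁻¹` plus `(G_blend⁻¹ − A22⁻¹)` on the genotyped block, with
  `G_blend = 0.95 G + 0.05 A22`. No τ/ω block weighting is applied. The
  construction is verified in tests against the dense inverse of the
  explicitly assembled joint-distribution H.
- Dense inversion goes through Cholesky; a reciprocal-condition estimate
  (LAPACK `pocon`) below 1e−10 raises a singularity error carrying the
  smallest eigenvalue rather than silently regularizing.

### The transformation and its diagnostics

`K* = wK + α11′ + βI` probes how the element distribution of K (or K⁻¹)
drives h² and the EBV spread; it is a probe, not a tuning device. The study
grid is w ∈ {0.9, 1, 1.1}, α, β ∈ {−0.05, 0, 0.05}; for pedigree matrices
α = −0.05 (negative off-diagonals) and the cell (α = 0, β = −0.05)
(diagonals below 1) are excluded — α = 0.05 with β = −0.05 stays in. The
useful exact algebra: α shifts every element (D = μ(diag) − μ(offdiag)
unchanged), β shifts only the diagonal (D changes by exactly β), w scales
both D and the implied genetic variance. Since the intercept contrast
annihilates `11′`, a REML fit with the mean as the only fixed effect is
exactly invariant to α as long as K* stays invertible; β is absorbed into
the residual (`σ²g K + (σ²e − βσ²g) I`), so ĥ²(β) = σ²g/(σ²g + σ²e − βσ²g),
strictly increasing in β. The grid runners report singular or indefinite
cells as rows with condition diagnostics (smallest eigenvalue, PD flag)
instead of failing; only a broken baseline cell aborts a run.

In the K⁻¹ grid, EBVs per cell are predicted with the baseline h² — the
published comparison, mimicking routine evaluations where variance
components are not re-estimated — and additionally with the cell's own REML
h², which restores the baseline EBVs exactly for pure rescalings. Both
columns are emitted, labeled `slope`/`pearson_r` and `slope_own`/
`pearson_r_own`.

### Summaries

Off-diagonal statistics count each unordered pair once (upper triangle);
standard deviations are sample sds (ddof = 1). The concentration band is the
open interval (−0.02, 0.02) by default. The extreme-row discard experiment
removes, in a single pass on the original matrix, every row/column whose
diagonal exceeds the threshold or that participates in any off-diagonal
below the floor, together with the corresponding phenotypes.

## The simulator

`simulate_population` emulates a discrete-generation livestock scheme: 100
male + 100 female founders by default, ten generations, the top 50% of
females selected as dams on their own phenotype (founder females, who have
no phenotypes, are selected at random), each dam mated 1:1 to a randomly
drawn male with a litter of four, offspring sex equiprobable. True breeding
values follow `u = (u_s + u_d)/2 + m`, `var(m) = (1 − (F_s + F_d)/2) σ²g/2`,
with inbreeding tracked exactly through an incrementally built A. Phenotypes
are `y = μ + u + e`, missing for all founders and for 25% of males. Markers
are neutral, unlinked, gene-dropped from founder alleles with per-locus
founder frequency uniform on (0.05, 0.95); genotypes are retained for
generations 8–10 only. In the masked pedigree 10% of sire links and 5% of
dam links (generations ≥ 1) are set unknown. All randomness flows from a
single seed; identical config + seed reproduces every output bit-for-bit.

True variance components default to h² = 0.30 with phenotypic variance
42.25 around a mean of 48 (phenotype summary μ ± sd ≈ 48 ± 6.5). Under
this generative rule the realized population is ~2,200–2,400 individuals
with ~600–760 genotyped; totals are realization-dependent, not targets.

What the simulator does *not* emulate: linkage and QTL architecture (trait
values are pedigree-based, keeping A, G and H mutually consistent in
expectation), overlapping generations, selection on EBVs, genotyping errors
and missing genotypes. Passing tests therefore demonstrate the internal
consistency of the matrix/REML/BLUP machinery and the distributional
mechanisms under these idealized conditions, not robustness to real-data
artefacts.

A note on masking direction: with a pedigree-only analysis, masking parent
links *raises* the apparent h² on these simulations (understated
relationships require a larger σ²g to match the observed family
covariances). The reduction of h² under masking appears in the single-step
analysis, where the genomic block anchors the genotyped generations and the
sparser A-part carries less structure — that is the configuration in which
the masked-versus-full comparison is tested here.

## Problem sizes and numerical choices

Test and example analyses use populations of 150–350 individuals, where a
full grid run takes seconds; the full-scale reference design (~2,200+
individuals, 5,000 markers) is exercised by the parameter-recovery and
H⁻¹-concentration checks and by `scripts/acceptance.py`, each replicate
taking a few seconds. Ties in dam selection are broken by sort order (a
measure-zero event for continuous phenotypes); matings sample males without
replacement unless fewer males than dams are available. Degenerate inputs
surface as typed errors: cyclic or unordered pedigrees, monomorphic marker
panels (zero G denominator), zero phenotypic variance, non-PSD kinships,
thresholds that would discard every row.

## Known limitations

- REML covers exactly one genetic random effect plus a residual; no
  multi-trait models, extra random effects, or fixed effects beyond the
  mean.
- Dense linear algebra throughout: fine to a few thousand individuals, not
  for national-evaluation scale; no sparse A⁻¹ pipelines, metafounders or
  unknown-parent groups.
- The optional loader for externally exported wheat-style data (dense A,
  0/1 genotypes, single-trait phenotypes) treats the supplied A as given,
  including whatever inbreeding its source pedigree implied.
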