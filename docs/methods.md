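# Methods

## Model

The evaluation model is a weighted random-regression (SNP-BLUP) model. For
`n` individuals and `N` biallelic loci with allele counts `x_ij ∈ {0,1,2}`
and counted-allele frequencies `p_j`,

    y = 1 μ + V b + e,
    v_ij = (x_ij − 2 p_j) (2 p_j (1 − p_j))^(γ/2),
    b ~ N(0, I σ_a²/s_γ),   e ~ N(0, D σ_e²),   D = diag(1/wt_i),

with `s_γ = Σ_j (2 p_j (1 − p_j))^(γ+1)`. The scaling exponent `γ` runs over
`[−1, 0]`: `γ = 0` is plain centering (RRc), `γ = −1` standardises each
locus to unit variance under Hardy–Weinberg proportions (RRcs). The weight
`wt_i` is the effective number of records behind phenotype `i` — for a
daughter-yield-deviation phenotype, the daughter count — so a heavier record
has residual variance `σ_e²/wt_i`.

The per-marker variance `σ_a²/s_γ` is the unique choice that makes the
marker model equivalent, at every `γ`, to the individual-level GBLUP model
`y = 1μ + g + e`, `g ~ N(0, G σ_a²)` with `G = V V′/s_γ`: under
Hardy–Weinberg and linkage equilibrium each locus contributes genetic
variance `(2p_j q_j)^(γ+1) σ_a²/s_γ`, which sums to `σ_a²`, and `E[diag G] ≈ 1`.
At the endpoints `s_0 = Σ 2p_j q_j` and `s_−1 = N`, i.e. the two classical
(VanRaden) relationship-matrix divisors. Allele substitution effects are
`ASE_j = b̂_j (2 p_j q_j)^(γ/2)` (the identity at `γ = 0`), and DGV are
`V b̂`, excluding `μ̂`; predicted phenotypes are `DGV + μ̂`.

The solver uses the marker-level mixed-model equations when `N ≤ n` and the
equivalent `n × n` generalised-least-squares system otherwise; the two
routes agree to numerical precision (tested to 1e−8 on DGV). Back-solving
from individual solutions, `b̂ = s_γ⁻¹ V′ G⁻¹ ĝ`, reproduces the direct
marker solutions to 1e−6 and uses a pseudo-inverse (relative cutoff 1e−10)
when `G` is singular, which is the normal situation when `n` exceeds the
rank of the coded matrix.

## REML

Variance components are estimated by restricted maximum likelihood for the
intercept-only fixed design. The weights are folded into the model by
pre-multiplying with `D^(−1/2)`; one eigendecomposition of the folded
relationship matrix then makes every likelihood evaluation O(n). The total
variance and the intercept are profiled out analytically, leaving a
one-dimensional bounded Brent search over `ln(σ_a²/σ_e²) ∈ [−10, 10]`
(convergence tolerance 1e−8, no random initialisation — fits are
deterministic). The reported restricted log-likelihood includes all
constants, so values are comparable across `γ` (the fixed design does not
change) and match a dense determinant evaluation (tested to 1e−6).

A caution on identifiability: with very heavy weights (e.g. ~549 effective
daughters per record, the generator's default) each record's residual
variance `σ_e²/wt` is tiny relative to the genetic variance, and the profile
restricted likelihood becomes nearly flat in `h² = σ_a²/(σ_a² + σ_e²)` above
`h² ≈ 0.5`; the unit-weight residual variance is then essentially
unidentified, while `μ`, effects and DGV remain well determined. For this
reason the heritability-recovery tests simulate single own records
(unit weights), the design under which `h²` is identifiable; applied
analyses with heavy weights should treat the estimated `h²` (not the fit or
predictions) with suspicion.

## Closed-form shrinkage-ratio theory

Treating one locus at a time (linkage equilibrium; Hardy–Weinberg; record
information independent of genotype), the scalar ridge estimates under the
two codings give

    ASE_scaled / ASE_unscaled = (c n + S/(2 p q)) / (c n + N),
    c = h²/(1−h²),  S = Σ_j 2 p_j q_j,

where `n` counts equally-informative records (a weighted generalisation
replaces `c·n·2pq` by `c·Σ_i wt_i·2pq`; with unit weights the two coincide).
`S = N·E[2p(1−p)]` is determined by the allele-frequency spectrum on the
grid `p = k/2n, k = 1..2n−1`:

- uniform spectrum (dense SNP arrays): `E[2p(1−p)] = 1/3` (continuous limit
  of the grid sum);
- U-shaped spectrum (sequence variants): Wright's stationary mutation–drift
  density `φ(p) ∝ p^(4Ne·v−1)(1−p)^(4Ne·v−1)` with zero selection, giving
  `E[2p(1−p)] = 2C(2n−1)` where the exact normaliser `C` is the reciprocal
  of a grid sum. When `4Ne·v ≈ 0` the sum telescopes into the harmonic
  number `H_{2n−1}`, giving the closed form
  `C* = (1/4n)(ln(2n−1) + 1/(4n−2) + γ_EM)⁻¹`; the package switches to the
  exact grid summation (with a warning) when `4Ne·v ≥ 1e−3`, and the two
  paths agree to better than 0.1% for `n` from 10² to 10⁶. The
  Euler–Mascheroni constant is hard-coded to 20 digits and named
  `EULER_MASCHERONI`, distinctly from the scaling exponent `gamma`, because
  both are conventionally written γ.

The ratio depends on the locus only through `p(1−p)`, exceeds 1 for rare
alleles, and equals 1 exactly at `p = (1 − √(1 − 2E))/2` with
`E = E[2p(1−p)]` — ≈ 0.211 for the uniform spectrum, 0.065 (n = 1000) and
0.041 (n = 100 000) for the U-shaped spectrum with `Ne = 65`, `v = 1e−8`.
Defaults `Ne = 65` and `v = 1e−8` describe an intensively selected
livestock population (`4Ne·v = 2.6e−6`).

## Synthetic data

The generator emulates a progeny-test evaluation: `n` individuals, one
weighted phenotype each, `N` loci in Hardy–Weinberg and linkage equilibrium
with frequencies drawn from the uniform or U-shaped spectrum on the `1/2n`
grid (the same support the theory sums over). True effects are drawn with
`Var(a_j) ∝ (2 p_j q_j)^(γ_true)` and deterministically rescaled so
`Σ 2 p_j q_j Var(a_j)` equals the total additive variance: `γ_true = 0` and
`γ_true = −1` are precisely the priors of the unscaled and scaled models, so
recovery of `γ_true` by the scan is a well-posed test. Residuals are
`N(0, σ_e²/wt_i)` with `σ_e² = σ_a²(1−h²)/h²`. Weights are constant
(default 549, an average effective daughter count) or 1 + Poisson(mean − 1).
All randomness flows from a single seed through independent child streams;
replicates are bitwise reproducible.

What the generator does **not** emulate: linkage disequilibrium (the theory
assumes none; with LD and MAF-dependent allele coding the single-locus
ratio is biased), pedigree/family structure, selection (the spectrum drops
the selection term), genotyping error or missingness, and multi-trait
phenotypes. Passing tests therefore demonstrate correctness of the
machinery and of the theory under its own assumptions, not the magnitude of
scaling effects in any real, LD-structured population.

## Scaling-parameter scan

The scan evaluates the grid `γ = −1, −0.9, …, 0` (step configurable) with
variance components re-estimated by REML at every grid point, under two
criteria: the restricted log-likelihood on the full data, and the weighted
mean squared error of prediction `Σ wt(pred − obs)²/Σ wt` on an
ordered train/validation split (input order as the age proxy; an explicit
id-list split is also supported). Validation predictions use the training
GLS intercept and the train–validation relationship block. Allele
frequencies for the coding come from the full data by default
(training-only is a flag) — with frequencies fixed, the scan is a fair
comparison of codings, not of frequency estimates. Ties on a criterion are
broken toward the more negative `γ`. Failed grid points are recorded as NaN
and skipped by the optimum.

## Per-MAF comparison

Loci are grouped by exact sample MAF (discrete on the `1/2n` grid), with an
optional bin width for small datasets; each group reports its mean MAF, the
Pearson correlation, the mean and median of per-locus ratios (zero
denominators excluded and counted), and the OLS slope (intercept included —
the convention adopted here) of one ASE vector on the other. The median is
reported alongside the mean because per-locus ratios are heavy-tailed when
the reference ASE is near zero; on small simulated datasets the median is
the statistic that tracks the theoretical curve. Groups below the minimum
size stay in the table, flagged, with statistics set to NaN.

## Numerical choices and problem sizes

- Eigendecomposition symmetrises its input and clips tiny negative
  eigenvalues to zero before use.
- `solve_snp_blup` uses a Cholesky factorisation of the phenotypic
  covariance on the individual-level route; a singular system raises rather
  than silently regularising.
- Variant filters (defaults: ≥5 minor-allele copies and all three genotype
  classes observed) run before coding; frequencies are recomputed on the
  retained loci. Monomorphic loci are always removed, with the reason
  logged in the removal report.
- Test and demonstration problem sizes are 50×200 up to 2000×500 for the
  equivalence and oracle suites, 20 replicates of 500×1000 for heritability
  recovery, and 10 replicates of 500×2000 for the `γ_true` recovery at each
  endpoint — sizes at which every suite completes in seconds to a few
  minutes on one CPU while keeping Monte-Carlo error well inside the
  asserted margins.

## Limitations

- The theory is single-locus; no attempt is made to model the covariances
  among estimated ASE that LD induces.
- The U-shaped spectrum is implemented for zero selection only; fitting the
  spectrum's parameters to an observed frequency distribution is out of
  scope.
- `h²` from heavily weighted records is weakly identified (see REML above).
- The pipeline targets datasets that fit in memory as dense matrices;
  biobank-scale streaming and PLINK binary formats are out of scope.
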