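# asescale

Scaling of allele counts in genomic evaluation changes the estimated allele
substitution effects (ASE) of rare variants — even though the direct genomic
values (DGV) barely move. `asescale` implements the machinery to study and
quantify that effect: a weighted SNP-BLUP/GBLUP solver with a continuous
scaling exponent, ASE back-solving, closed-form shrinkage-ratio theory under
uniform and U-shaped allele-frequency spectra, per-MAF comparison statistics,
and model selection for the scaling exponent by restricted likelihood and by
prediction error. A synthetic-data generator produces weighted, progeny-test
style datasets (daughter-yield-deviation phenotypes with effective record
counts) so the whole pipeline is testable without any external data.

## The model

Genotypes are allele counts `x_ij ∈ {0, 1, 2}`. The evaluation model is the
weighted random-regression (ridge) model

```
y = 1μ + V b + e,   b ~ N(0, I σ_a² / s_γ),   e ~ N(0, D σ_e²),
v_ij = (x_ij − 2p_j) · (2p_j(1−p_j))^(γ/2),   s_γ = Σ_j (2p_j(1−p_j))^(γ+1),
```

where `D = diag(1/wt_i)` carries the effective record count of each
phenotype, `p_j` is the counted-allele frequency and `γ ∈ [−1, 0]` is the
scaling exponent: `γ = 0` centers only (RRc; the ASE are the estimated
effects directly), `γ = −1` centers and scales each locus to unit variance
(RRcs; ASE are recovered as `b̂_j / √(2p_j(1−p_j))`). With the genomic
relationship matrix `G = V V′ / s_γ` the model is identical to GBLUP/GREML,
and effects can be back-solved from the individual solutions:
`b̂ = s_γ⁻¹ V′ G⁻¹ ĝ`.

Because the common ridge penalty `λ = σ_e² s_γ / σ_a²` acts on the coded
scale, the two codings shrink a given locus differently. Treating loci in
isolation (linkage equilibrium, Hardy–Weinberg), the ratio of the
scaled-coding ASE to the unscaled-coding ASE at a locus with frequency `p` is

```
ratio(p) = (c·n + S / (2p(1−p))) / (c·n + N),    c = h²/(1−h²),
```

with `n` records, `N` markers and `S = Σ_j 2p_j(1−p_j)`. `S/N` is the
spectrum's expected heterozygosity: `1/3` for a uniform spectrum and
`2C*(2n−1)` for the U-shaped mutation–drift spectrum, where
`C* = (1/4n)(ln(2n−1) + 1/(4n−2) + γ_EM)⁻¹` (Euler–Mascheroni constant
`γ_EM`) approximates the spectrum's normalising constant when `4·Ne·v ≈ 0`.
The ratio exceeds 1 for rare alleles, crosses 1 where `2p(1−p)` equals the
expected heterozygosity, and tends to 1 as the information `c·n` grows.

## Worked example

```python
from asescale import (FrequencyModel, GammaScan, SimulationConfig, SNPBLUP,
                      apply_variant_filters, crossing_maf, overall_comparison,
                      ratio_ushaped, simulate_dataset)

model = FrequencyModel("ushaped", ne=65, mutation_rate=1e-8)
config = SimulationConfig(n_individuals=500, n_snps=2000, h2=0.5,
                          gamma_true=-1.0, frequency_model=model, seed=1)
data = simulate_dataset(config)
genotypes, _ = apply_variant_filters(data.genotypes)   # ≥5 minor copies etc.

rrc = SNPBLUP(gamma=0.0).fit(genotypes, data.phenotypes.y,
                             sample_weight=data.phenotypes.weights)
rrcs = SNPBLUP(gamma=-1.0).fit(genotypes, data.phenotypes.y,
                               sample_weight=data.phenotypes.weights)
report = overall_comparison(rrc.result_, rrcs.result_, bin_width=0.05)
print(f"DGV correlation (RRc vs RRcs): {report.dgv_correlation:.4f}")
print(f"ASE correlation (RRc vs RRcs): {report.ase_correlation:.4f}")
low = report.per_maf.dropna(subset=['mean_ratio']).iloc[0]
print(f"lowest-MAF bin (mean MAF {low['maf']:.3f}): mean ASE ratio {low['mean_ratio']:.2f}")

scan = GammaScan(criterion="both", train_fraction=0.6).fit(
    genotypes, data.phenotypes.y, sample_weight=data.phenotypes.weights)
print(f"best gamma by restricted log-likelihood: {scan.best_gamma_loglik_}")
print(f"best gamma by weighted MSEP:             {scan.best_gamma_msep_}")

print(f"theoretical ASE ratio at p=0.5 (h2=0.2, n=1000, N=15M, U-shaped): "
      f"{ratio_ushaped(0.2, 1000, 15_000_000, 0.5, model):.3f}")
print(f"ratio crosses 1 at MAF {crossing_maf(model, 1000):.3f} (n=1000, U-shaped)")
```

Output:

```
DGV correlation (RRc vs RRcs): 0.9795
ASE correlation (RRc vs RRcs): 0.7935
lowest-MAF bin (mean MAF 0.032): mean ASE ratio 6.00
best gamma by restricted log-likelihood: -0.9
best gamma by weighted MSEP:             -0.7
theoretical ASE ratio at p=0.5 (h2=0.2, n=1000, N=15M, U-shaped): 0.244
ratio crosses 1 at MAF 0.065 (n=1000, U-shaped)
```

Reading this: the genomic values from the two codings correlate at 0.98
while the effect estimates correlate much less, and the rarest variants
(MAF ≈ 0.03) get ASE about six times larger under scaled coding — the
shrinkage difference the closed-form ratio predicts. The data were generated
with an architecture matching `γ = −1` (each locus contributes equal
expected variance), and both selection criteria point near that endpoint.
The theory lines say that at a common allele (p = 0.5) scaled coding
*under*-states the ASE (ratio 0.24 for a sequence-density panel), and that
the two codings agree at MAF 0.065 for a 1000-individual U-shaped spectrum.

The same pipeline is scriptable from the shell:

```
asescale simulate --n 500 --snps 2000 --h2 0.5 --gamma-true -1 \
    --freq-model ushaped --seed 1 --out-prefix demo
asescale fit --genotypes demo.vcf --phenotypes demo.phenotypes.tsv \
    --gamma -1 --out-prefix demo_rrcs
asescale theory --scenario 0.2,1000,15000000 --dist ushaped --out curve.tsv
asescale scan --genotypes demo.vcf --phenotypes demo.phenotypes.tsv \
    --criterion both --out scan.tsv
asescale run --out-dir full_run --seed 1     # simulate→fit→compare→scan
```

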