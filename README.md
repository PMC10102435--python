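# bgpwas

Bayesian genome–phenome wide association (BGPWAS) for plant diversity
panels: instead of testing one trait against millions of variants, each
candidate variant is tested once against the *entire* phenome, revealing
pleiotropy and producing a trait signature per variant.  The package also
prepares and imputes the phenome (kinship-aware multi-trait imputation)
and screens coding InDels for protein-truncating, putative
loss-of-function consequences.

## The model

For a variant with alternate-allele dosage `y ∈ {0,1,2}^n` the package
fits the reverse regression

    y_i = X_i β + ε_i,   ε_i ~ N(0, σ²)

where the columns of `X` are the standardized traits (e.g. 124 of them)
plus the top 3 leave-one-chromosome-out (LOCO) principal components for
the variant's chromosome.  Coefficients carry a horseshoe prior

    β_j | λ_j, τ ~ N(0, λ_j² τ²),   λ_j ~ C⁺(0, 1)

whose global scale is set from the expected number of associated traits
`p₀` (the least integer value of 10% of the predictor count `D`):

    τ₀ = p₀ / (D − p₀) · 1/√n

Null traits are shrunk hard toward zero while truly associated traits
escape through the heavy half-Cauchy tails.  Bayesian ridge (`N(0, 5)`)
and lasso (Laplace, rate tuned by a χ²₁ prior) are available for
comparison.  A trait is called **significant** when its central 95%
posterior interval excludes zero.  Posterior draws come from exact
auxiliary-variable Gibbs samplers; R-hat and effective sample size are
reported per coefficient.

Upstream, missing phenotype values are imputed under a multi-phenotype
mixed model `Y = Sβ + ε` with `S ~ MN(0, K, I)` (kinship-structured
latent factors), `β ~ MN(0, I, τ⁻¹I)` and a Wishart(p+5, ¼I) prior on
the residual precision, fitted by a monotone penalized-EM scheme;
missing entries get their posterior-mean prediction and observed values
are never altered.  Downstream, InDels are mapped into spliced coding
sequences (strand-aware, VCF anchor convention), the mutant CDS is
translated, and calls are classified (frameshift / in-frame /
stop-gained / stop-lost / noncoding) with the truncation fraction and
any protein domains lost.

## Worked example

Simulate a 150-accession panel with a causal variant (`Chr01_600`)
shifting traits 1 and 5 by 0.8 standard deviations per dosage copy,
impute the masked phenome, and run the per-gene scan:

```bash
bgpwas simulate --n 150 --n-variants 120 --p 8 \
    --causal-variant 5 --causal-traits 1,5 --effect 0.8 \
    --seed 3 --out-prefix sim
bgpwas impute --phenotypes sim.phenotypes.tsv --vcf sim.vcf \
    --max-iter 150 --out-prefix sim
bgpwas run --phenotypes sim.imputed.tsv --vcf sim.vcf \
    --region Chr01:550-650 --flank-bp 100 \
    --chains 2 --iterations 1000 --seed 3 --out assoc.tsv
```

The association table (`assoc.tsv`, one row per variant × predictor)
flags exactly the injected trait pair on the causal variant:

```
variant_id predictor  post_mean  q025  q975
 Chr01_600  trait001      0.268 0.180 0.359
 Chr01_600  trait005      0.356 0.265 0.440
```

`post_mean` is the posterior mean regression coefficient of the trait in
the dosage regression; the interval `[q025, q975]` excludes zero for the
two injected traits and covers zero for every other trait and for the
neighbouring null variant.  Headers record the tool version, a config
hash, the seed and τ₀, so reruns are byte-identical.

Consequence screening takes a VCF + GFF3 + FASTA:

```bash
bgpwas consequence --vcf indels.vcf --gff3 genes.gff3 --fasta ref.fa \
    --domains domains.tsv --out calls.tsv
```

and reports, per coding InDel, the class, mutant/reference protein
lengths, the truncation fraction (e.g. a frameshift that stops at 60% of
the native length has truncation 0.40) and domains fully or partially
lost.

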