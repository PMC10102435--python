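# Methods

## Reverse regression with shrinkage priors

The association unit is one variant. Its dosage vector `y` (alternate
allele counts, kept on the 0..2 scale) is regressed on the full set of
standardized traits plus the leave-one-chromosome-out principal
components of the variant's chromosome:

    y_i = X_i β + ε_i,  ε_i ~ N(0, σ²).

The model carries an implicit intercept with a flat prior: `y` and the
columns of `X` are centered before sampling, which integrates the
intercept out exactly and leaves the slopes unchanged. This matters in
practice — dosages have mean ≈ 2·f and traits associated with the
variant acquire nonzero means, and without the intercept those means
leak into the slope estimates.

Three prior families are implemented, each with its exact
auxiliary-variable Gibbs sampler:

* **Horseshoe** — `β_j | λ_j, τ ~ N(0, λ_j²τ²)`, `λ_j ~ C⁺(0,1)`,
  sampled through the inverse-gamma parameter expansion of the
  half-Cauchy (each `λ_j²` and its auxiliary are conjugate
  inverse-gamma draws). The global scale is fixed at
  `τ₀ = p₀/(D−p₀)·n^{-1/2}` with `p₀ = max(1, floor(0.1·D))` by
  default; a half-Cauchy(0, τ₀) hyperprior on τ is available
  (`PriorSpec(tau_hyperprior=True)`). Fixing τ is the default because
  the scaling rule already encodes the expected sparsity; the hyperprior
  mode covers the common alternative. Both interpretations of "least
  integer value of 10%" are reachable through `p0_frac`.
* **Ridge** — `β_j ~ N(0, 5)`, a single conjugate Gaussian draw.
* **Lasso** — Laplace coefficients via the Park–Casella
  inverse-Gaussian mixture; the squared rate `λ²` carries a χ² prior
  with one degree of freedom (prior expectation 1) and is updated by a
  conjugate Gamma draw.

The residual sd has a half-t(3, sd(y)) prior, handled with the standard
inverse-gamma augmentation. Defaults are 4 chains × 2000 iterations
(half warmup), seeded through `numpy.random.SeedSequence` spawning so
runs are bit-reproducible. Split-R̂ is computed in-package; bulk ESS
comes from arviz. Any coefficient with R̂ > 1.05 raises a warning, never
a silent pass.

Significance is the central 95% quantile interval excluding zero; an
HPDI option exists (`call_significant(..., method="hpdi")`). The
quantile rule is the normative one; the HPDI matches what interval plots
typically display. No multiple-testing correction is applied across
variants or traits — false-positive control is delegated to the
regularizing prior, which the null-calibration test verifies directly
(flagged fraction ≤ 2% at n=200, D=50).

Variants within a gene (or window) are fitted independently, never as a
multi-response model: per-variant fits parallelize trivially and avoid
the sampling pathologies of jointly modelling highly collinear variants
from one locus.

## Phenome preparation and MPMM imputation

Traits with more than 30% missing data are removed (strictly greater
than; the boundary survives). Of each pair of traits with pairwise-
complete Pearson |r| > 0.95, the later column is dropped — a greedy scan
in column order, deterministic for a fixed column order; pairs sharing
fewer than 3 observations count as uncorrelated and are logged. Each
remaining trait is centered and scaled to sd 1 (n−1 denominator), and
the (mean, sd) pairs are stored for back-transformation. Constant traits
are rejected by name.

Imputation uses the multi-phenotype mixed model

    Y = U + ε,  U = Sβ,  S ~ MN(0, K, I_r),  β ~ MN(0, I_r, τ⁻¹I_p),
    ε ~ MN(0, I_N, E),  E⁻¹ ~ Wishart(p+5, ¼I_p),

with K the VanRaden kinship. The fit is a deterministic penalized-EM:

* **E-step** (exact): for every missingness pattern, the missing entries
  of a row given its observed entries are Gaussian; their conditional
  means fill the matrix and their conditional covariance (the Schur
  complement of `E_oo` in `E`) is accumulated into the scatter matrix.
  Omitting that covariance mass (i.e. treating the filled values as
  data) is degenerate — the residual covariance then collapses onto its
  prior floor and the imputations diverge — which is why a joint-mode
  (ICM) scheme was rejected.
* **M-steps** (block ascent): S solves a Sylvester system in the
  eigenbasis of K (zero kinship eigenvalues force the corresponding
  latent rows to zero); β solves a second Sylvester system mixing the
  factor Gram matrix with τE; E takes the Wishart-regularized mode
  `(R'R + C + V₀⁻¹)/(N + ν₀ − p − 1)`.

Each sweep cannot decrease the observed-data penalized log-likelihood,
so the recorded objective trace is monotone; convergence is declared at
relative change < 1e-6 (default cap 1000 sweeps, and the fit reports
which criterion ended it). Observed entries are never modified; missing
entries receive the final posterior-mean prediction.

**Latent rank.** The default rank is `min(N, ceil(p/2))`, not full rank.
With r = p the point-estimated factors can absorb the entire signal,
leaving residuals (and hence E) pinned to the prior floor and the
masked-entry predictions unidentified; empirically, recovery on a
correlated 20-trait phenome falls from r ≈ 0.9 at rank p/2 to ≈ 0.05 at
rank p. Full rank remains available via `MPMMSpec(rank=...)`. τ defaults
to 1 and is exposed; neither the rank nor τ used on real panels is
prescribed by the method, so both are configuration.

Imputation runs once on the full phenome before any association run; no
re-imputation per gene.

## Genome side

Dosage encoding is the alternate-allele count per genotype; missing
genotypes are a contract violation (inputs are expected to be imputed
upstream, e.g. by Beagle) rather than silently filled. Multi-allelic
records decompose into one record per alternate allele. Upstream
site-quality filters are assumed already applied; only the MAF filter
(retain MAF ≥ 0.1) is implemented because association runs need it.

Kinship is the VanRaden centered GRM, `K = ZZ'/(2Σf_j(1−f_j))` with
`Z = G − 2f`, the standard population-genetics construction.
Monomorphic columns contribute nothing and an all-monomorphic input is
an error. LOCO PCs for chromosome c are the top eigenvectors (default 3)
of the GRM built from all variants *not* on c, scaled by the square root
of their eigenvalues; eigenvector signs are fixed by making the
largest-magnitude loading positive, so outputs are reproducible.
Column centering makes scores mean-zero and mutually orthogonal by
construction, and corrupting chromosome c never changes chromosome c's
scores — exclusion is strict, which the tests assert bitwise.

## Consequence calling

A variant's reference span is mapped into the spliced CDS; minus-strand
genes reverse-complement both alleles and map through reversed exon
order, with the VCF anchor base landing at the 3′ end of the
transcript-oriented allele. InDels overlapping an exon boundary are
rejected explicitly rather than guessed — their effect on the mature
transcript depends on splicing outcomes the model does not represent.
Translation uses the standard table, stops at (and excludes) the first
stop codon, ignores a trailing partial codon, and attaches a stop-lost
note when no in-frame stop is reached.

Classes follow fixed rules: frameshift iff the allele length difference
is not a multiple of 3 (this rule wins over any downstream stop);
in-frame changes are deletion/insertion, stop-gained when an early stop
appears, stop-lost on read-through, synonymous-boundary when the
protein is unchanged. The truncation fraction is
`1 − len(alt protein)/len(ref protein)` on stop-free lengths (negative
for elongations). Domain intervals are user-supplied reference-protein
coordinates; a domain starting beyond the mutant protein's last residue
is lost in full, one ending beyond it is partial. The deleted reference
substring is reported verbatim so representation-level discrepancies
between pipelines stay visible.

## Synthetic data

The generator exists so every contract is testable without external
downloads, and its writers emit the same plain-text formats the real
parsers read (VCF, phenotype TSV, GFF3, FASTA).

* **Populations** — binomial(2, f) dosages with per-variant frequencies
  uniform in a MAF range; optional demes draw per-deme frequencies from
  a Balding–Nichols beta (default F_st 0.2–0.35 in tests), which gives
  genuine kinship blocks. No linkage disequilibrium is simulated:
  variants are independent given the deme, so windowed "genes" have
  uncorrelated variants — recovery results say nothing about fine-mapping
  under LD.
* **Phenomes** — forward simulation of the imputation model itself
  (kinship-structured factors plus Gaussian residuals). A fixed loading
  matrix can be supplied; the identity produces per-trait independent
  genetic effects (diagonal genetic covariance), the regime in which
  kinship is the *only* route to a masked entry and the kinship-vs-
  identity comparison is informative.
* **Causal effects** — `trait += effect · dosage`, applied to the
  standardized phenome so effects are in trait-sd units per allele copy.
* **Missingness** — MCAR uniform or block-structured, with held-out true
  values recorded for scoring. Real phenome missingness is unlikely to
  be MCAR; recovery numbers here are upper bounds in that respect.
* **Toy genes** — random valid ORFs (ATG...stop, no internal stop)
  split across exons inside a synthetic chromosome, with labelled
  candidate InDels (frameshift deletion and insertion, codon-aligned
  in-frame deletion, intronic control).

### Study conditions for the end-to-end check

The full-pipeline recovery check uses n=200 accessions, 300 variants on
2 chromosomes, a 20-trait phenome, 5 test variants of which one is
causal for two traits at standardized effect 0.8, 10% MCAR missingness,
and 10 seeds. The phenome is a rank-3 factor model with unit loadings
and unit residual sd (so roughly three-quarters of each trait's variance
is shared structure) and the causal variant has MAF ≥ 0.3 — a
moderately heritable, correlated trait panel of the kind multi-year
diversity-panel phenomics produces. In a nearly-uncorrelated phenome the
same effect size leaves each causal trait's partial evidence near the
detection boundary, because the two causal traits compete to explain the
same dosage; shared trait structure is what lets the regression isolate
the dosage component of each causal trait.

## Numerical and runtime choices

Tests and the acceptance script run the samplers at 2 chains × 800–1000
iterations; with D ≤ 50 predictors the Gibbs conditionals are small
Cholesky solves and a full fit takes well under a second, so the
reduced settings keep the whole suite in the low minutes while R̂ stays
below 1.05 for essentially all coefficients. Kinship eigenvalues are
clipped at zero after verifying the smallest is above −1e-8 (scaled);
prior variances inside the samplers are clipped to [1e-12, 1e12] to
keep the Cholesky factorizations finite in the deep tails. Degenerate
inputs fail loudly by design: constant responses, constant traits,
non-PSD kinship, all-monomorphic genotype matrices, fewer informative
dimensions than requested PCs, exon-boundary-spanning InDels.

## Known limitations

* No LD, selection, or multi-environment structure in the simulations.
* MAP-EM imputation underestimates its own uncertainty relative to a
  full variational treatment; only posterior-mean imputations are
  consumed downstream.
* The consequence caller does not model splice-site disruption,
  start-codon loss beyond the generic rules, or isoform choice beyond
  the supplied gene models.
* Reverse-regression significance is conditional on the included trait
  set: a flagged trait means "informative about the dosage given the
  other traits", which is the pleiotropy signature the method is
  designed to expose, not a marginal GWAS claim.
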