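# Methods

`invkit` genotypes polymorphic chromosomal inversions from SNP genotype
matrices.  An inversion is treated as a biallelic locus with non-inverted
(N) and inverted (I) alleles.  Because crossing-over is suppressed in
N/I heterozygotes, the two allele classes accumulate independent variation
inside the inverted segment and behave as two diverged haplotype pools.
The package implements the two complementary detection strategies built on
this footprint, a generator of synthetic cohorts with exactly this
structure, and the validation and association layers around them.

## Haplotype-clustering caller (constrained mixture model)

### Embedding

Within a candidate region, pairwise identity-by-state (IBS) distances are
computed between individuals: `d_ij = mean over shared called SNPs of
|g_i − g_j| / 2`, where g are alleleB dosages.  The measure is invariant to
which allele is counted at any SNP.  Classical (Torgerson) multidimensional
scaling of this matrix — eigendecomposition of `B = −½ J D∘D J` — gives the
sample coordinates; principal-component scores of the mean-imputed, centered
dosage matrix are an equivalent alternative, and for Euclidean distances of
centered dosages the two coincide up to column sign.  Each component's sign
is fixed so that its largest-magnitude score is positive; nothing downstream
may depend on eigenvector orientation.  Two components are retained by
default: inversion state typically loads on the first, and (in structured
cohorts) ancestry on the second, but state and ancestry can load on
different components, so the count is configurable.

One caution that the package's own simulations expose: IBS distance is an
L1 (city-block) metric, so the MDS embedding of a lattice of cluster
centers (3 genotypes × G ancestries) is not a perfect orthogonal grid —
genotype and ancestry directions tilt into each other.  The model layers
below are therefore written to tolerate tilted, per-group cluster axes.

### The constrained three-cluster mixture

On embedding coordinates y (N × k), the model is a three-component Gaussian
mixture with two hard constraints reflecting the genetics:

* mixture weights follow Hardy–Weinberg equilibrium in a single inverted-
  allele frequency f: `w = ((1−f)², 2f(1−f), f²)`;
* cluster means are collinear and equidistant: `μ_j = a + j·b` for
  j ∈ {0 (NN), 1 (NI), 2 (II)} — adding one inverted haplotype moves an
  individual by the same displacement b.

Fitting is by EM.  The E-step is standard.  The M-step is closed-form:

* `f = (Σ_i r_i,II + ½ Σ_i r_i,NI) / N`, the maximizer of the expected
  multinomial log-likelihood under the HWE weight constraint (clamped to
  [1e−6, 1−1e−6] so no weight degenerates);
* (a, b) solve a 2×2 weighted-least-squares system per dimension
  (per-cluster precision weights enter only in the per-cluster-covariance
  mode, fitted as a conditional ECM step);
* covariance per mode: shared isotropic, shared diagonal (default; it
  stabilizes small clusters) or per-cluster diagonal, floored at a small
  epsilon with a warning on collapse.

Both constraints hold *exactly* at every iteration by construction, and the
observed-data log-likelihood is non-decreasing (ordinary EM; ECM in the
per-cluster mode).  The fit records its iteration history on request so the
test suite can assert both properties directly.

Initialization projects samples onto the first component (or the highest-
variance direction) and cuts at the 1/3 and 2/3 quantiles; restarts place
the cuts at the HWE quantiles of a random starting frequency plus jitter,
because pure jitter around 1/3–2/3 cannot reach strongly skewed-f optima.
The best of `n_restarts` log-likelihoods is kept.

### Signal detection and calling

A region shows an inversion signal when the constrained three-cluster model
beats a single Gaussian by BIC: `ΔBIC = BIC_null − BIC_fit > 0`, strictly,
with no intermediate evidence categories.  BIC counts only free parameters:
f (1), means (2k), covariance (1, k or 3k); the null uses k + covariance.

Genotype calls are argmax posteriors; samples whose maximum posterior falls
below `call_threshold` (default 0.9) are left uncalled.  Component j=0 — the
cluster carrying weight (1−f)² — is labeled NN.  **Which cluster is
physically inverted is not identifiable from SNP data**: the fitted labeling
is a consistent biallelic convention, and anchoring it to physical
orientation needs external reference genotypes (experimental assays in the
original studies).  Consequently all accuracy evaluations against simulated
truth resolve the single global label flip (f ↔ 1−f with NN ↔ II) first.

### Ancestry-controlled model

In admixed cohorts the region's haplotypes carry ancestry structure that
confounds a single three-cluster fit.  The joint model adds a latent
ancestry class g with its own allele frequency and cluster geometry:

    p(y, x) = Σ_g π_g · N(x; ν_g, τ_g²) · Σ_j w_j(f_g) · N(y; μ_gj, Σ_g)

where x is a scalar ancestry-informative variable — by default the second
embedding component, or any external score — and y are the retained
embedding components.  The equidistance constraint applies per ancestry in
all components of y, which is what lets the model absorb the lattice tilt
noted above.  EM runs over the G×3 latent classes; when hard ancestry
labels are supplied the ancestry layer is clamped to them.  G can be fixed
or chosen over {1, 2, 3} by BIC of the joint fit.  With G = 1 the model
reduces exactly to the unstratified fit (the x-layer factorizes out), which
the tests verify via the y-marginal log-likelihood.

Degeneracy guard: G·3 latent classes are refused when they exceed N/5, and
an ancestry group left empty at initialization reduces G with a warning.

## LD breakpoint scan

The second detector does not use the interior haplotypes; it looks for the
disruption of block adjacency at the breakpoints.  Four blocks of
`block_size` SNPs (default 10) flank a candidate breakpoint pair: A just
outside-left, B just inside-left, C inside-right, D outside-right.  On a
chromosome carrying the inversion the segment is reversed, so B and C swap
their adjacencies: A becomes adjacent to C and B to D.

Within each block, haplotype pairs per individual are reconstructed with
the standard EM for multilocus haplotype frequencies from unphased
genotypes (random pairing), each individual keeping its most probable pair
(lexicographic tie-break); haplotypes rarer than `min_haplotype_freq`
(default 0.05, which keeps the multinomial tables estimable at N in the
hundreds) are pooled into one class.  Individuals with too many
heterozygous block sites fall back to genotype-vector classes with a
warning.

The model at one breakpoint pair treats each chromosome's four block
classes as observations.  Null model: two independent multinomials over the
adjacent pairs (A,B) and (C,D).  Inversion model: a per-chromosome latent
carrier indicator with prevalence ρ; non-carrier chromosomes follow the
adjacency multinomials, carrier chromosomes follow cross multinomials over
(A,C) and (B,D).  The phase linking the four within-block pairs into two
chromosomes is unobserved and is summed over as a latent variable (all
distinct assignments; at most 8 per individual).  Both models are fitted by
EM; `ΔBIC = BIC_null − BIC_inv > 0` is the signal, with BIC on 2N
chromosomes and multinomial cells minus one per table plus one for ρ.  With
ρ fixed at 0 the inversion model's likelihood equals the null's exactly — a
nesting identity the tests assert to 1e−9.

This likelihood is a deliberately simplified reconstruction of the
LD-disruption idea (the original scan's exact likelihood lives in its own
software, not reproduced here).  Two consequences are documented rather
than hidden:

* the carrier/non-carrier labeling is nearly symmetric when the outside
  blocks are uninformative (swapping roles with ρ → 1−ρ changes the
  likelihood only through the adjacency structure), so carrier
  responsibilities are reported up to that orientation, and cross-method
  agreement is evaluated after aligning it;
* candidates whose blocks partially overlap the true segment retain most of
  the signal, so the ΔBIC surface is a plateau around the truth and
  localization is limited to roughly the block size.

A scan maps the model over a grid of breakpoint pairs whose separations are
fixed fractions of the region (defaults 0.4–0.9, the window sizes used for
known inversions) stepped by `step` SNPs, and summarizes the best candidate
per window fraction.

## Synthetic cohorts

The generator produces the exact statistical structure both methods assume,
with known truth:

* a shared ancestral haplotype per region; the inverted-pool founder
  differs from it at each segment site independently with probability
  `pool_divergence` (this founder split is shared across ancestries — the
  inversion predates the ancestry split);
* each ancestry perturbs both of its pool founders with one flip pattern at
  rate `ancestry_divergence`, displacing ancestries roughly orthogonally to
  the genotype axis;
* pool members are mosaics of founder copies mutated at `within_pool_mut`
  per site, recombined only within a pool — crossovers never join different
  pools inside the segment;
* individuals draw an ancestry (or, with probability `admix_fraction`, two
  different ancestries, one per haplotype), inversion alleles under
  HWE(f_ancestry), and haplotypes from the matching pools; dosage is the
  haplotype sum;
* trios: parents as above, the child inheriting one haplotype per parent
  with its pool label (within-pool recombination only);
* phenotypes: a recessive binary outcome with
  `logit P(case) = logit(baseline_prev) + log(OR)·1[II]`, or a quantitative
  trait dichotomized strictly below a percentile of its realized values.

This is a star-shaped founder-divergence model, not a coalescent.  It
reproduces the three-cluster embedding footprint, the per-ancestry cluster
lattice, Mendelian transmission and the cross-breakpoint LD disruption, and
it keeps ground truth exact.  It does **not** reproduce realistic background
LD decay (flanking blocks are nearly monomorphic apart from mutation
noise), recurrent inversions, or gene conversion inside heterozygotes —
so passing tests demonstrate correctness of the inference machinery under
the stated model, not performance on real cohort LD structure.

### Default study conditions

| scenario | settings | rationale |
| --- | --- | --- |
| single-ancestry recovery | N=1000, 300 SNPs, f=0.4, pool divergence 0.05, mutation 0.005 | well-separated three-cluster setting; divergence of ~13 segment sites vs within-pool noise of ~3 |
| two-ancestry calling | N=1500, f = 0.48 / 0.74, pool divergence 0.15, ancestry divergence 0.02 | an old, deeply diverged inversion whose divergence dominates the region, with a smaller ancestry perturbation — the geometry reported for the archetypal ancestry-structured inversion |
| breakpoint scan | N=300, 120 SNPs, carrier allele frequency 0.3, pool divergence 0.3 | the scan needs every 10-SNP flanking block to contain divergent sites (expected 3 per block here); at low divergence a block is uninformative with probability (1−d)^10 and the candidate goes silent |
| association | N=2000, recessive OR=2, baseline prevalence 5% | the low-trait percentile design with a recessive inversion effect |

Problem sizes throughout (SNP counts, replicate counts) are chosen so the
whole simulation-backed test battery runs in minutes on one core while
keeping every rate estimate's binomial noise well inside the asserted
margins.

## Validation and association

* **Mendelian consistency**: a trio is consistent iff the child's genotype
  is producible from one allele of each parent; trios with any uncalled
  member leave the denominator.
* **Concordance**: exact 3-class accuracy plus carrier-status (NI or II vs
  NN) sensitivity/specificity against reference genotypes.
* **Percentile case definition**: cases strictly below the
  linear-interpolation quantile of the trait; ties at the threshold are
  controls.
* **Genetic-model tests**: logistic regression of the binary outcome on the
  coded genotype (recessive 1[II], dominant 1[NI or II], additive dosage),
  optional numeric covariates, Wald 95% CI and p-value.  Quasi-separation is
  flagged and the CI reported as unbounded rather than fabricated.
* **Stratified analysis** per stratum with small strata skipped;
  **fixed-effect combination** by inverse-variance pooling of log-ORs
  (two identical studies shrink the SE by exactly √2), with pooled
  individual-level regression with cohort indicators available as the
  alternative.
* **Attributable risk**: Levin's formula `PAR = p(OR−1)/(1+p(OR−1))` with p
  the exposure prevalence in controls.
* **Multiple genetic models**: max-|z| permutation correction over the
  three codings (default 1000 permutations) or Bonferroni ×3.

## Numerical choices

* f clamped to [1e−6, 1−1e−6]; variances floored at 1e−10 with warnings.
* EM convergence: relative log-likelihood change below 1e−8 (mixture) /
  absolute haplotype-frequency change below 1e−8 (block EM).
* Ties in haplotype-pair assignment break lexicographically; ties at the
  case-definition threshold resolve to control.
* Degenerate inputs are contracts, not crashes: fewer than 10 samples,
  non-finite coordinates, zero-variance matrices, empty regions, blocks
  that do not fit, single-class blocks (BIC difference reported missing)
  and all-missing pairs are all rejected or flagged explicitly.

## Known limitations

* Physical inversion orientation (which haplotype pool is inverted) is not
  identifiable from SNP data; external reference genotypes are required to
  anchor the labeling.
* The LD-scan likelihood is a simplified variant (see above) with carrier-
  label symmetry and block-size-limited localization.
* The simulator's flat background LD makes the scan's flanking blocks less
  informative than in real data at low divergence.
* One inversion per region; the six-cluster multi-haplotype patterns of
  some known inversions are out of scope, as are phasing, imputation and
  genome-wide scanning performance.
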