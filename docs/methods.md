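# Methods

## Scope and data model

`ailhap` analyzes a phased, imputed mapping population descended from two
diverged founder populations.  Inputs are a phased VCF (strictly
biallelic; heterozygous genotypes must carry the `|` separator — the
loader refuses to impute or re-phase), a phenotype table (one continuous
trait plus sex and batch factors), a genetic map (bp ↔ cM,
non-decreasing), optionally an external local-ancestry table and a GTF.
Coordinates are 1-based inclusive in VCF/GTF space; internal variant
ordinals are dense and 0-based per chromosome.  The only variant filter
applied post-phasing is minor allele frequency, with a strict `>`
threshold (so `maf_min=0` still removes monomorphic sites); sequencing
quality and missingness filters belong to upstream raw-data processing,
and post-imputation data are assumed complete.

## Haplotype blocks

Each chromosome is tiled with non-overlapping windows of `block_size`
consecutive SNPs (default 5, chosen to match the physical scale at which
r² decays to ~0.1 in a ninth-generation intercross).  Trailing SNPs that
do not fill a block are dropped rather than merged, keeping every block
at the same degrees of freedom; chromosomes shorter than one block
contribute none.  Block alleles are exact strings in REF/ALT bases; no
mismatch tolerance is applied, and block numbering restarts per
chromosome.

## Diversity and dissimilarity

Pooled haplotype homozygosity per block uses descending allele
frequencies p₁ ≥ p₂ ≥ …:

    H12   = (p₁+p₂)² + Σ_{i≥3} pᵢ²,
    H123  = (p₁+p₂+p₃)² + Σ_{i≥4} pᵢ²,
    H1234 = (p₁+p₂+p₃+p₄)² + Σ_{i≥5} pᵢ².

When a block has fewer alleles than the pool size the statistic equals 1
(the formula does this automatically).  Between-population dissimilarity
per block: Jaccard distance 1 − |A∩B|/|A∪B| on allele sets;
Jensen–Shannon divergence ½KL(A‖M) + ½KL(B‖M), M = (A+B)/2, natural
logarithm (range [0, ln 2]), with 0·log(0/·) := 0; Bray–Curtis
1 − 2Σmin/(Σ+Σ).  Two deliberate conventions:

* `jensen_shannon` implements the divergence itself; several numerics
  packages return its square root by default, so a `sqrt` flag exposes
  that variant, and no claim is made about which convention underlies any
  published table.
* Population-level Bray–Curtis compares **relative abundances**, not raw
  counts: with panels of very different sizes (e.g. 30 founder vs 600
  admixed haplotypes) the raw-count statistic saturates toward 1 from the
  size imbalance alone.  The low-level `bray_curtis` still accepts raw
  counts for equal-mass comparisons.

Genome-level summaries are unweighted means over blocks, labeled as such
in output; random within-population comparisons use equal-size disjoint
halves under a stored seed.

## Local ancestry

Each haplotype receives per block a posterior probability of descending
from the HQLA line.  The built-in classifier is intentionally simple: the
block allele's Laplace-smoothed frequency in each founder panel,
f_P = (count_P + c)/(n_P + 2c) with pseudocount c (default 1), combined
with equal class priors into posterior = f_HQLA/(f_HQLA + f_HB).  Smoothed
frequencies rather than smoothed counts keep the priors equal when panel
sizes differ.  An optional running-mean smoother over an odd number of
blocks (default 1 = off, so the contract stays at block resolution)
borrows strength along the chromosome; windows truncate at chromosome
ends.  This is not a reimplementation of CRF-based ancestry inference —
output from such tools can be imported instead (whitespace table, two
posterior columns per haplotype, windows mapped to blocks by midpoint
containment; the dialect is pinned by a test fixture).

Hard calls threshold the posterior at 0.5 with ties assigned to HQLA
(origin = 1 iff posterior ≥ 0.5); diploid ancestry codes are the sum of
the two haplotype origins (0/1/2 copies of HQLA ancestry).  Accuracy can
be scored against simulator truth or, as on real data, against
haplotype-blocks carrying alleles unique to one founder panel.  The two
scores differ in meaning: block alleles present in both panels are
genuinely ambiguous (the Bayes-optimal call is still wrong for some
carriers), so truth-based accuracy is bounded below 1 whenever the
founder pools share block alleles, while panel-unique accuracy is 1 by
construction for the built-in classifier in the small-pseudocount limit.

## Relationship matrices

All three constructions are exchangeable inputs to the mixed model:

* SNP GRM: G_jk = (1/M) Σ_m (x_jm − 2p_m)(x_km − 2p_m)/(2p_m(1−p_m))
  over polymorphic SNPs (the per-marker-standardized estimator; documented
  so ports match).
* Ancestry GRM: the same estimator with diploid ancestry codes in place
  of dosages, skipping blocks fixed for one origin — it captures global
  ancestry so the per-block origin test is conditioned on it.
* Haplotype matrix: per block, haplotype alleles score 1 when identical,
  0 otherwise, giving Γᵢ (2N×2N, sample-major haplotype order); Γ is the
  block average, accumulated streaming so Γᵢ is never materialized for
  all blocks.  H = KΓK′/2 with K = I ⊗ [1 1] reduces to summing each
  2×2 sample sub-block and halving; diagonals lie in [1, 2], equal to
  1 + (own cross-haplotype identity).

All outputs satisfy a PSD tolerance (min eigenvalue ≥ −1e−8·trace/N).

## Mixed-model association

The model is y = Qα + xβ + g + e, Q = intercept + sex + batch dummies,
g ~ N(0, σ²_g K).  Variance components are estimated by profiling the
restricted likelihood over δ = σ²_e/σ²_g using a single eigendecomposition
of K; δ is located on a 49-point log₁₀ grid over [−6, 6] and refined by
bounded scalar minimization (absolute tolerance 1e−8 in log₁₀ δ).
Degenerate inputs (constant phenotype, rank-deficient design) raise
rather than returning garbage.

Dosage scans (SNP and ancestral modes) use the EMMAX-style approximation:
δ is fixed from the covariate-only REML fit, the system is whitened, and
each marker is tested by weighted least squares with the residual scale
re-estimated per marker and a t reference on N − p − 1 df.  This choice
makes the scan collapse exactly to OLS when K = I, which the tests
exploit as an oracle.  Monomorphic markers yield NA rows.

Haplotype-block tests code each individual's allele combination
(unordered pair) as a categorical factor; combinations carried by fewer
than `min_count` individuals (default 5) pool into one OTHER level.  Both
the null (Q + polygenic, with the haplotype H matrix) and the alternative
(adding the combination dummies) are refit by full ML — REML likelihoods
are not comparable across fixed-effect structures — and twice the
log-likelihood gap is referred to χ² with (retained levels − 1) df.
Blocks with a single level after pooling are reported untestable (NA)
rather than given p = 1.  Aliased dummies are pruned with the df adjusted
accordingly.

FDR control is Benjamini–Hochberg across markers/blocks (NA p-values
excluded and never significant); significant entries within `gap` block
indices on a chromosome (default adjacent) merge into regions reported
with their span and minimum p.

## Block-wise effect estimation

For one block, y = Qα + Z_d μ + e with Z_d the copy-count matrix over
alleles (plain mode) or allele×origin labels "<seq>_<0|1>" (ancestral
mode); rows always sum to 2, and the ancestral coding marginalizes to the
plain one.  Carrier-free columns are dropped at fitting time (the coding
itself keeps them, matching the standard presentation of the matrix).  μ
is i.i.d. Gaussian; λ = σ²_e/σ²_μ is re-estimated per block by REML on
V = σ²_μ ZZ′ + σ²_e I using the same eigendecomposition core, and BLUPs
with prediction-error SEs come from the mixed-model equations.  BLUPs are
shrunken — they approach 0 as λ → ∞ and their norm is monotone
non-increasing in λ — so planted effects are recovered in sign and order
but biased toward zero.  Each allele also receives a founder-exclusivity
flag (HQLA-only / HB-only / shared / novel) from the panel spectra.

## Ancestry-based dominance

Phenotypes are first replaced by least-squares residuals of
trait ~ intercept + sex + batch (aliased columns of a confounded design
are dropped with a warning).  Per block, individuals split into the three
ancestral classes by diploid code; blocks with any class below
`min_class` (default 5) are reported untested.  A tie-corrected
Kruskal–Wallis test screens blocks, BH-FDR is applied to the screening
p-values (the conservative placement of the single stated FDR step), and
survivors get Steel–Dwass all-pairs post-hoc tests at nominal α = 0.05:
each pair is ranked jointly, the tie-corrected standardized rank-sum
statistic t is referred to the studentized range with k groups and
infinite df via q = |t|√2.  A permutation mode replaces the normal
calibration of t by its permutation distribution (mid-p, half-weight on
ties, appropriate when comparing a discrete permutation tail to the
continuous reference) and then applies the same family correction; it is
intended for minimum class sizes ≲ 8.

Labels: **high-parent** dominance requires the heterozygote median to
exceed both homozygote medians with both het-vs-homozygote contrasts
significant; **mid-parent** dominance requires the heterozygote median to
strictly exceed the midpoint of the two homozygote medians with the
het-vs-nearer-homozygote contrast significant.  The certifying contrast
for mid-parent is genuinely a design choice (the definition names no
test); "nearer homozygote" is the default because it is the weakest
contrast consistent with the claim, and `mid_rule` exposes "higher" and
"both" alternatives.  High-parent implies mid-parent by construction.
Note that a strongly additive locus can satisfy the mid-parent rule
through sampling noise around the midpoint — the rule is deliberately
permissive, and the high-parent label is the stringent one (under purely
additive simulated architecture high-parent labels stay at or below the
FDR level; this is asserted in the tests).

## Annotation

Gene features are read from GTF (via an in-memory feature database);
regions and genes are 1-based closed intervals and any ≥1 bp overlap
counts, strand ignored.  Lookup uses an interval tree, checked against
brute-force pairwise overlap in the tests.  A total chromosome-naming
mismatch raises with a hint, since silent zero-overlap is the common
failure mode.

## Simulator

The generator reproduces the study design's structure at desk scale, with
known truth:

* **Founders.**  Per chromosome, SNP alt-allele frequencies are drawn
  from a U-shaped Beta(0.5, 0.5) prior; each line owns a pool of 8
  distinct chromosome haplotypes, the two pools sharing a configurable
  fraction (default 0.33) of haplotypes.  Founder individuals (default
  16 HQLA + 14 HB) draw each chromosome uniformly from their pool.  The
  pool model (rather than a coalescent) yields the low within-line
  diversity and strong block-level differentiation characteristic of
  divergent selected lines.  Note that distinct pool haplotypes can
  still coincide within a 5-SNP window, so block-level allele sharing
  exceeds the chromosome-level sharing fraction — as in real data, where
  a third of block alleles were shared between lines.
* **Gene dropping.**  F1 crosses HQLA dams with HB sires pair by pair
  (so every F1 is an ancestral heterozygote at every block); later
  generations (default to F9) pair males and females at random with
  balanced family contributions — the standard AIL maintenance design
  that maximizes effective size — at 200 breeding individuals per
  intermediate generation (the order of the genotyped parental
  generation in such designs), with a final generation of 585.  Each
  meiosis draws a Poisson(map length in Morgans) crossover count with
  positions uniform in cM and no interference; there is no mutation and
  no selection.  Every transmitted SNP carries its founder population of
  descent, and block-level truth is the origin at the block's middle SNP
  (recombination within a block makes the block label ambiguous for that
  haplotype anyway).
* **Phenotype.**  y = mean (1000 g) + sex effect (150 g for males)
  + batch effect (3 batches: 0/+20/−20 g) + origin/allele-tied additive
  block effects + heterozygote bonuses at planted dominance blocks
  + a polygenic term drawn with SNP-GRM covariance (default σ²_g = 6400)
  + Gaussian noise (default σ²_e = 10000), i.e. a body-weight-like scale
  with heritability ≈ 0.4.  The full genetic-value decomposition is
  stored per individual.

What the simulator does **not** emulate: genotyping error and
missingness, phasing and imputation error, selection during line
maintenance, mutation, sex-specific recombination maps (a per-sex map is
accepted on input but the generator emits a single map), and realistic
genome size (two 100 cM chromosomes by default).  Tests passing on this
generator therefore demonstrate correctness of the statistical machinery
under clean ancestry and complete phased data, not robustness to upstream
data-quality failure modes.

## Problem sizes and determinism

The test suite and the acceptance script run simulations of 2 chromosomes
× 200–400 SNPs with 300–500 final individuals — sizes at which every
mixed-model fit is seconds — and drive all randomness from explicit
seeds; reruns are byte-identical.  The genome-wide ancestry-balance check
uses the balanced design (15 + 15 founders, 500 F9): at this scale the
Monte-Carlo SD of the HB:HQLA ratio from drift is ≈ 0.07, so the expected
ratio of 1 is verified within a ±0.1 band.
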