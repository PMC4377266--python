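# Methods

## Data model

A *contact zone* is a set of individuals of one species, each with an id,
planar coordinates in metres, and a cytotype label (2x/4x/5x/6x, the set is
open).  Around each individual, the vascular plant species present within a
0.2 m radius are recorded; a species table carries six ordinal indicator
values (T, L, F, R, N, H; 1 = low … 5 = high) describing temperature, light,
soil moisture, soil reaction, nutrient and humus preferences.  A dominant
marker matrix holds 0/1 band phenotypes per individual and locus, with
replicate-pair links and per-locus / per-individual reproducibility flags.

## Niche construction

The niche vector of an individual is the unweighted arithmetic mean of its
accompanying species' indicator values, the target species always excluded.
Missing indicator values are handled *per indicator*: the mean for, say, L
is taken over the species that have an L value.  This keeps all the
information a plot offers rather than deleting whole species listwise, and
matches standard indicator-value practice.  An individual is dropped from
niche analyses — with a logged warning, never an exception — when it has no
usable accompanying species or when some indicator has no value among them
(a complete 6-vector is required downstream).  Dropped individuals remain
in the spatial and marker analyses, so each stage reports its own n.

## Pillai–Bartlett MANOVA

For responses `p`, groups `g`, total `n`: with between/within cross-product
matrices `B` and `W`, the trace is `V = Σ λᵢ/(1+λᵢ)` over the eigenvalues of
`W⁻¹B` (computed as the symmetric generalized eigenproblem `(B, W)`; a
rank-deficient `W` is reported as an error suggesting removal of constant
or collinear columns).  The F approximation uses `s = min(p, g−1)`,
`m = (|p−g+1|−1)/2`, `n′ = (n−g−p−1)/2`:

    F = ((2n′+s+1)/(2m+s+1)) · (V/s)/(1−V/s),
    df1 = s(2m+s+1),  df2 = s(2n′+s+1).

For two groups and six responses this gives `df2 = n − 7`.  p-values come
from the F distribution (the permutation machinery exists separately for
the cross-scale test).  The implementation is validated against a
definitional eigendecomposition oracle (≤ 1e−10) and against statsmodels'
MANOVA, and reduces to one-way ANOVA η² for a single response.

## PCA and niche breadth

PCA operates on the column-standardized (zero-mean, unit-variance, ddof=1)
niche matrix via SVD; explained variance fractions equal the correlation-
matrix eigenvalue shares and sum to 1.  Constant columns are dropped with a
warning.  Orientation is made reproducible by forcing the largest-magnitude
loading of each component positive.  Group ellipses are summarised by the
score-space centroid and per-component SD.  Niche breadth of a group is the
mean Euclidean distance of its members to their centroid over *all* retained
components, with SE = sd/√n; a single-member group has an undefined SE,
reported as missing.

## Mantel test

Segregation is tested by correlating geographic distance with the binary
cytotype distance (0 same, 1 different).  The statistic is Kendall's
**tau-b** on the strict lower triangles: with an almost entirely tied 0/1
matrix, tau-a would be deflated by ties by construction.  The null permutes
*individuals* — rows and columns jointly of one matrix — which preserves
distance-matrix structure (the standard Mantel null), 999 permutations by
default.  The upper-tail p-value uses the add-one rule
`p = (#{r* ≥ r} + 1)/(n_perm + 1)`, so `p ∈ [1/(n_perm+1), 1]` and finite
permutations can never report p = 0.  A single-cytotype input has zero
variance in the cytotype distance and is an error.

## Cross-scale Monte Carlo test

Hypothesis: niche differentiation in the contact zone is *smaller* than
across the range-wide distribution; the test is therefore lower-tailed.
Each of 9999 permutations draws, without replacement and per cytotype,
exactly the contact-zone counts from the range-wide pool of those cytotypes
and records the subsample's MANOVA F;
`p = (#{F* ≤ F_contact} + 1)/(n_perm + 1)`.  Sampling without replacement
mimics drawing distinct individuals from a survey.  Contact-zone
individuals are not excluded from the pool by default (an option exists).
Note an edge case: if the pool *is* the contact zone, the subsample is the
whole pool every time and the null distribution is degenerate at the
empirical F; the exchangeable null for validation is instead "contact zone
drawn as a random per-cytotype subsample of a larger pool", which is how the
type-I test suite constructs it.

## Hybrid-category model for dominant markers

Six categories with fixed Mendelian ancestry-state expectations
φ = (both copies pool 0, one each, both pool 1): Pure0 (1,0,0), Pure1
(0,0,1), F1 (0,1,0), F2 (¼,½,¼), BC0 (½,½,0), BC1 (0,½,½) — no
second-generation backcrosses.  With per-locus null-allele (band-absence)
frequencies f₀, f₁ in the parental pools, a band is observed iff at least
one gene copy is non-null, so `P(no band | class) = φ₀f₀² + φ₁f₀f₁ + φ₂f₁²`.
The band probability is non-increasing in both frequencies.

Inference is Gibbs sampling with latent-genotype augmentation, chosen for
exact conjugate steps: per sweep, (i) per-cell ancestry states and
null/non-null allele pairs given current classes and phenotypes, (ii)
conjugate Beta updates of f₀, f₁ from latent allele counts and a Dirichlet
update of the mixing weights π from class counts, (iii) class labels `z`
from their conditional given the fresh f and π, with latent genotypes
marginalised analytically through the closed-form band probability.
Ordering matters: the frequency updates condition on the current labels
*before* the labels are refreshed, so an explicit `init_z` genuinely
selects a mode — with symmetric priors the two parental labellings are
exchangeable, and swapped initialisation swaps the pure-class assignments.
Label orientation against an anchor cytotype is a post-hoc relabelling
(`orient_posterior`), never a prior.

Priors are uniform — Beta(1,1) on each frequency, symmetric Dirichlet(1) on
π — as the neutral reading of "default settings, without prior
information"; a Jeffreys option (½) is exposed.  Posterior class
probabilities are post-burn-in visit frequencies of `z`; the modal class
breaks exact ties by fixed class order (logged).  Non-convergence is
surfaced through stored π/f traces, not raised.  Numerical guards: f is
clipped to [1e−9, 1−1e−9] inside likelihoods and no-band probabilities to
[1e−12, 1−1e−12] before logs.

Polyploid phenotypes are scored with the two-allele (diploid-equivalent)
dominant likelihood — a deliberate modelling simplification: allele dosage
in 4x/5x/6x individuals is not modelled, and loci are treated as unlinked.

Default run length is 100,000 sweeps with 10,000 burn-in, a desk-scale
setting under which the validation suites below are stable; production-style
long runs (e.g. 1.3 million sweeps after 100,000 burn-in) are plain
parameters.  The bundled analysis scripts use 30,000/3,000, which on the
default synthetic zone (183 × 129 after QC) reproduces the generating
classes essentially perfectly.

Validation: on 2-locus problems with fixed f and π the sampler matches an
exhaustive-enumeration posterior (all ancestry states × allele
configurations) within ±0.02 at 100,000 sweeps; on two well-differentiated
pools (40+40 individuals, 200 loci, mean |f₀−f₁| ≥ 0.6, 20,000 sweeps)
≥ 95% of pure individuals are recovered with posterior ≥ 0.9 and the F1
posterior beats both pure classes for ≥ 90% of F1s.

## Marker QC

Replicate error rate = mismatches / phenotypic comparisons over all
replicate pairs × loci scored in both profiles.  The fragment filter
removes, in order: loci flagged nonreproducible, monomorphic loci, then
singleton loci (band present in exactly one individual or absent in exactly
one); category counts always sum to the input locus count.  A companion
individual filter drops profiles flagged nonreproducible and prunes their
replicate links.  In the pipeline the error rate is computed first (on all
scored fragments), then replicate rows are collapsed, individuals filtered,
fragments filtered.

## Synthetic generator

The generator *defines the study conditions*; its defaults emulate a
tetraploid/hexaploid contact zone with a pentaploid strip (90/26/74
individuals, Gaussian spatial clusters of SD 4 m spaced 14 m apart, 0.2 m
plots).  A latent environmental gradient (default 0.05 indicator units per
metre) runs across the zone; each individual's local environment is the
gradient at its position plus its cytotype's niche shift (default ±0.3
around the centre, 3× larger in the range-wide pool) plus N(0, 0.25²)
plot-level noise.  Species (pool of 60) have optima uniform over the
realised gradient range; presence follows a logistic response exp-quadratic
in (environment − optimum) with response width 1.0 and a baseline offset of
−0.8 chosen to give ≈ 6–15 accompanying species per plot; empty plots are
topped up with the best-matching species so niche vectors are always
defined.  Indicator values are the species optimum mapped to [1, 5],
coupled to the gradient with per-indicator strengths (1.0 … 0.3), jittered
N(0, 0.6) and rounded to the ordinal scale — correlated but not collinear
responses.  Markers: per-locus f₀/f₁ supplied or drawn Beta(0.5, 0.5)
independently per pool; phenotypes flipped with per-call error 0.016 (two
independent error realisations per replicate pair give a mismatch rate of
≈ 2·0.016·0.984 ≈ 3.1%); flagged/singleton/monomorphic fragments are
appended and recorded in the truth file.

What the generator does *not* emulate: real community assembly, dispersal
kernels, spatial autocorrelation of the environment beyond the linear
gradient, allele-dosage signal in polyploid band intensities, or
multi-generation pedigrees.  Passing recovery tests therefore show the
estimators are correct under their own model assumptions, not that those
assumptions hold in any particular field system.

## Determinism and numerics

Every stochastic component takes a seed; the pipeline derives per-stage
seeds from one master seed via `SeedSequence.spawn`, and identical config +
seed reproduce byte-identical output tables.  Permutation p-values use the
add-one rule throughout.  MANOVA subsample F values in permutation loops
are computed by a lean path sharing the cross-product code with the public
API.

## Known limitations

* The diploid-equivalent marker likelihood ignores dosage; posterior class
  labels for high-ploidy hybrids inherit that approximation.
* The MANOVA F approximation assumes multivariate normality of niche
  vectors; with ordinal indicator means on bounded support this is an
  approximation, mitigated by the moderate-to-large group sizes the design
  targets.
* Mantel tests with the binary distance measure association, not its
  spatial scale; no correlograms or partial Mantel variants are provided.
* The Gibbs sampler is single-chain; label consistency across runs is
  handled by post-hoc orientation, and multimodality diagnostics are
  limited to the stored traces.
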