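# Methods

## Model

The package implements a single-trait animal model

    y = Xb + W₁l + (W₂p) + W₃a + e,

with fixed effects (intercept, sex, optional covariates), a litter
(common-environment) random effect l ~ N(0, Iσ²_l), an optional pen effect,
additive genetic effects a ~ N(0, Hσ²_a) for every pedigree animal, and
residuals e ~ N(0, Iσ²_e).  Variance components are treated as known
inputs, as in routine genetic evaluation; only variance *ratios* enter the
mixed-model equations.  Multi-trait covariance structures are out of scope:
a study with several traits is run as independent single-trait layers over
the same pedigree and genotypes.

**H⁻¹** combines pedigree and genomic information:
H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A₂₂⁻¹] on the genotyped block.  A⁻¹ is assembled
sparsely by Henderson's rules with inbreeding (Mendelian-sampling variance
dᵢ = 0.5 − 0.25(F_s + F_d) with both parents known, 0.75 − 0.25F_p with
one, 1 otherwise); inbreeding coefficients come from a Meuwissen–Luo style
recursion and are cross-checked against the tabular A.  G is VanRaden
method 1 with counted-allele frequencies observed in the genotyped set —
the base-population frequencies are unknowable here, and G is invariant to
which allele is counted per SNP.  Before inversion G is blended with A₂₂
(default 95 % G + 5 % A₂₂) to guarantee positive definiteness.

**APY.**  The sparse inverse follows the core/noncore recursion
G_APY⁻¹ = [Gcc⁻¹ 0; 0 0] + [−Gcc⁻¹Gcn; I] Mnn⁻¹ [−GncGcc⁻¹ I] with
mᵢᵢ = gᵢᵢ − g_ic Gcc⁻¹ g_ci.  The core block is inverted via Cholesky (a
failure advises raising the blending weight); mᵢᵢ ≤ 1e−10 raises an error
naming the offending animal, because a noncore animal inside the span of
the core makes Mnn⁻¹ blow up.  The assembled matrix never stores a
noncore × noncore off-diagonal entry, so its nonzero count is bounded by
n_core² + 2·n_core·n_noncore + n_noncore.

**Core sizes** are the numbers of largest eigenvalues of the (pre-blend) G
whose cumulative sum first reaches 50/80/90/95/99 % of trace(G).  The
spectrum of G equals the squared singular values of the scaled centred
gene-content matrix, so this is the SVD criterion expressed on G; the
pre-blend matrix is used because blending deliberately inflates the bulk
of the spectrum.

**Core definitions.**  Eight strategies plus the FULL baseline; shared
conventions: deterministic given (inputs, seed), ties broken toward the
smaller animal id, and a pool smaller than the target returns the whole
pool with an explicit shortfall rather than failing (large-scale studies
show the same behaviour when eligibility filters bite).  Choices worth
recording:

* *MPA* ranks eligible animals (genotyped, both parents known, own record)
  by progeny count instead of using fixed progeny thresholds; thresholds
  tuned to one dataset do not transfer, ranking reproduces the intent for
  any dataset.
* *Ped* interprets "genealogical order" as topological id (birth) order and
  takes ranks ⌊(i + 0.5)·n/target⌋, which spreads the core across cohorts
  proportionally.
* *Unrel* auto-calibrates its relationship threshold by bisection until the
  greedy pairwise-constrained scan lands within 2 % above the target, then
  trims at random; an explicit threshold can be supplied instead.
* *Fam* groups genotyped full sibs by (sire, dam); animals with an unknown
  parent are singleton families.  With fewer families than the target the
  representatives are topped up at random.
* *QR* factorises the SNP-by-animal orientation of centred Z with
  column-pivoted (rank-revealing) QR so that pivots index animals; the
  first `target` pivots are the core.  The animal-by-SNP orientation would
  make the pivots index SNPs, which cannot define a core.

**Solver.**  Jacobi-preconditioned conjugate gradients on the sparse MME;
convergence is declared at squared relative residual ‖r‖²/‖rhs‖² ≤ 1e−12,
the convention of large-scale animal-breeding solvers.  Identifiability is
handled by constraining the first observed level of each categorical fixed
effect to zero (an intercept is always present).  Iteration counts are
reported per scenario but never asserted: they are diagnostics.

**Evaluation.**  Validation animals are the youngest cohort that is both
genotyped and recorded; their phenotypes are removed from the training
right-hand side (truncation), while a separate full-data regular-ssGBLUP
run supplies y_adj = y − Xb̂ − W₁l̂ (− W₂p̂), i.e. phenotypes adjusted for
all non-genetic effects with the additive part left in.  Accuracy is
corr(y_adj, GEBV)/h on the validation set; MSE is the mean squared
y_adj − GEBV difference.  Scenario similarity uses Pearson correlations of
GEBV over genotyped animals, and Ward (D2) hierarchical clustering of
scenario GEBV vectors via Lance–Williams updates on squared Euclidean
distances (the scipy implementation is kept as an independent oracle in
the tests).  MAF-spectrum overlap bins each SNP's minor-allele frequency
into [0, 0.1), [0.1, 0.2), [0.2, 0.3), [0.3, 0.4), [0.4, 0.5] — half-open
on the left so no SNP is double-counted, with 0.5 in the last bin — and
reports the fraction of SNPs whose bin agrees between core-only and
all-genotyped frequencies.  A SNP monomorphic within the core simply falls
into the first bin.

## Synthetic population

`synthpop` emulates a closed pig nucleus line with discrete generations:
founders, then each generation a fixed number of sires and dams drawn from
the previous one, each dam producing one full-sib litter.  Genotypes are
gene-dropped: founder haplotypes drawn per SNP from Uniform(0.05, 0.95)
allele frequencies (giving a full MAF spectrum for the overlap statistic),
gametes formed under the Haldane map (phase switches between parental
haplotypes with probability (1 − e^(−2d))/2 per marker interval,
independent across intervals, 0.5 across chromosome boundaries).  All SNPs
act as QTL with Gaussian effects, rescaled so the realized additive
variance equals h² on a unit phenotypic-variance scale — the
infinitesimal-like architecture under which GBLUP and the APY recursion
are exactly specified.  The sex effect is a single additive constant for
males (0.25 σ_p), exercising the fixed-effect machinery minimally.

Default scale (chosen once, for desk feasibility and to mirror the
structural regime of large evaluations):

| parameter | default | note |
|---|---|---|
| generations | 5 | founders + 4 |
| sires × dams per generation | 8 × 90 | Ne ≈ 29 |
| progeny per litter | 12 | ~1,080 born per generation |
| genome | 3 chromosomes × 0.25 M, 1,000 SNPs each | 4·Ne·L ≈ 90 segments |
| genotyping by generation | 0.1, 0.4, 0.6, 0.8, 0.95 | × 0.85 for females |
| phenotyping fraction | 0.35 | records independent of genotyping |
| h², litter fraction | 0.20, 0.10 | pen 0 by default |

This yields ~2,800 genotyped animals with an eigen-99 % dimensionality
near 700 — small relative to the genotyped count, as in real evaluations —
and, critically, eligible pools for the restrictive definitions (LPM, LPF,
MPA) at or above the eigen-99 core size, so shortfalls remain marginal
rather than dominating the comparison.  A validation cohort of ~330
animals keeps accuracy estimates stable across seeds.

What the generator does *not* emulate: selection on estimated breeding
values (matings are random, whereas real nucleus lines are under genomic
selection), mutation, dominance/epistasis, genotyping errors and
imputation, overlapping generations, and realistic genome length (a full
pig genome is ~20 M).  Passing tests therefore demonstrate the internal
consistency of the APY machinery and the qualitative size/definition
phenomena under an idealized additive population, not calibrated accuracy
levels for any real breed.

## Numerical choices

* Symmetry of relationship matrices is enforced to 1e−10; inverse checks
  in tests use 1e−8; matrices are symmetrised (½(M + Mᵀ)) after BLAS
  products to kill rounding asymmetry.
* Monomorphic SNPs are removed, never imputed: their term in the VanRaden
  denominator vanishes.
* A₂₂ is extracted from the full dense tabular A (fine up to ~20k
  animals); indirect methods for the very large case are out of scope.
* Eigenvalues are clipped at zero before cumulative sums; the size for
  threshold t is the smallest k with cumulative fraction ≥ t (a 1e−12
  slack absorbs rounding at t = 1).
* Sub-seeds derive from the master seed by fixed offsets per (stage,
  definition index, size index), so any scenario can be re-run in
  isolation and reproduce the full-factorial result exactly.
* APY fidelity is monitored in G-space (‖G_implied − G‖_F, where
  G_implied is the relationship matrix the APY inverse implies): this
  decreases monotonically as a nested core grows.  The inverse-space
  residual ‖G·G_APY⁻¹ − I‖ is *not* monotone — entries of the inverse
  scale with 1/mᵢᵢ, which diverges as noncore animals become spanned by a
  large core — and is therefore not used as a quality metric.

## Known limitations

* Single trait per solve; no multi-trait covariance, maternal, or
  genotype-by-environment effects.
* No REML/Gibbs variance estimation — ratios are inputs.
* Unknown-parent groups and metafounders are not implemented; founders are
  assumed to be one unrelated base population.
* The Unrel bisection assumes the greedy kept-set size is (weakly)
  monotone in the threshold, which can be violated in pathological G
  matrices; the implementation then returns the best threshold found and
  reports it.
* Desk scale throughout: dense G and A are held in memory; the pipeline is
  not meant for >20k genotyped animals.
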