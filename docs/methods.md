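# Methods

`mfstab` quantifies the stability of community composition and of ecosystem
multifunctionality in a designed pot experiment, and decomposes how plant
richness, drought and plant invasion act on multifunctional stability —
directly, and indirectly through the stability of the plant, litter-faunal
and soil-faunal communities. This note records the model, the numerical
choices, and what the synthetic-data generators do and do not emulate.

## The experimental design

The reference design crosses four plant richness levels (1, 2, 4, 8 species
from a 16-species pool) with three drought levels (coded 0/1/2) and two
invasion levels (0/1). A *complete set* holds one pot of each of 45 distinct
assemblages (16 monocultures, 10 two-species, 10 four-species and 9
eight-species mixtures); one complete set sits in each of the 3 × 2
treatment cells, giving 270 pots. The species composition of each mixture is
drawn once, seeded, without replacement; composition identity only matters
to the synthetic generator and to the one-to-one baseline mode.

## Similarity as stability

Every pot is summarized by four profiles: plant biomasses, litter-faunal and
soil-faunal abundances (each with a phylogeny), and 14 function variables.
Function variables are first rescaled to

    V' = (V - min V) / sd(V)

with the sample (n−1) standard deviation, so every function contributes
evenly to the global variance while staying nonnegative. Pairwise
similarities are then

* **community**: 1 − normalized weighted UniFrac between relative-abundance
  profiles, D(u,v) = Σ_b l_b|U_b − V_b| / Σ_b l_b(U_b + V_b) over branches b
  — the normalized variant, so D ∈ [0,1] and 1 − D is a valid similarity;
* **multifunctional**: 1 − Bray–Curtis dissimilarity of the V′ profiles;
* **single-function**: SIM_ij = 1 − |V_i − V_j|/(V_i + V_j), with 0/0
  defined as 1 (two absent quantities are maximally similar; warned).

Weighted UniFrac is computed in-package from the branch-indicator matrix
(per-branch subtended proportions, weighted city-block distance). This keeps
continuous biomass values exact; the implementation is cross-checked in the
test suite against an independent per-branch summation oracle on float data
and against scikit-bio on integer counts, where the two agree to machine
precision.

Three subsets of each similarity matrix operationalize three stability
aspects:

| aspect | pairs | covariates | n (reference design) |
|---|---|---|---|
| invariability | same (richness, drought, invasion) | richness, drought, invasion | 1476 |
| drought resistance | non-drought × drought pot, same (richness, invasion) | richness, invasion, drought = disturbed level (1 or 2) | 2148 |
| invasion resistance | non-invaded × invaded pot, same (richness, drought) | richness, drought | 1611 |

For a factor spanning the contrast, the pair takes the disturbed member's
level (drought resistance) or drops the factor when binary (invasion
resistance). Richness enters raw (1, 2, 4, 8) by default with a log2
option. Drought-resistance pairs keep the raw disturbed level {1, 2}
uncentred. Counts follow closed-form combinatorics (Σ C(k,2) within cells;
Σ k² across contrasted cells) and are verified against exhaustive
enumeration of all C(270,2) pot pairs.

The one-to-one baseline mode restricts cross-treatment pairs to pots
sharing an assemblage — the strict correspondence variant used to compare
the multivariate treatment of similarity against its univariate analogue.

## The path model

Each aspect's pair table feeds a recursive observed-variable path model
(`PathModel` → `PathResults`). Default structure: every treatment factor →
every community stability and → multifunctional stability; plant stability
→ both faunal stabilities; every community stability → multifunctional
stability. All variables are z-standardized; each endogenous variable is
regressed on its parents by least squares, so coefficients are standardized
partial regression weights (equal to ML path coefficients for a recursive
system with uncorrelated errors, and readable as partial correlations).
Exogenous covariances are fixed at their sample values.

Goodness of fit uses the ML covariance-structure discrepancy
F = ln|Σ̂| − ln|S| + tr(SΣ̂⁻¹) − p with χ² = (n−1)F,
df = p(p+1)/2 − (edges + exogenous (co)variances + residual variances), and
RMSEA = sqrt(max(χ²−df,0)/(df(n−1))) (0 when df = 0, with p_fit = 1).
A just-identified model yields χ² = 0 to numerical precision. Deleting a
path and refitting raises df by one; the χ² inflation measures how much the
model destabilizes without that path.

Effects on an outcome are decomposed over directed paths: the direct effect
is the single edge; each multi-edge path's coefficient product is
attributed to exactly one mediator — by default the *first* mediator after
the factor (so richness → plant → soil fauna → multifunctionality counts as
"via plant"; a last-mediator option is provided and flagged in output).
direct + Σ indirect = total holds exactly by construction. Percentage
shares are taken on the absolute total.

## Inference

**Mantel-like permutation test.** Under H0 "this factor has no effect on
this response", the pot labels of the response's similarity matrix are
permuted simultaneously over rows and columns; pairs are re-looked-up and
the model refitted, giving a null distribution for any direct, indirect or
total effect. By default only the tested effect's dependent matrix is
permuted, keeping the mediator structure intact; a permute-all-dependents
mode applies the same pot permutation to every endogenous matrix. The
sign-selected tail probability (1+b)/(m+1) is reported as `p_one_sided`;
the default `p_value` doubles it (capped at 1). The doubling matters:
choosing the tail after seeing the sign inflates the type-I error to ~10%
at a nominal 5%, which we measured directly under the zero-effect
generator; the doubled version is calibrated (measured 3–5% over 500 null
simulations × 199 permutations).

**Bootstrap.** Pots are resampled with replacement within each
(richness, drought, invasion) cell; pair sets are rebuilt from the
resampled pots (pairs formed by two copies of the same pot are dropped —
their similarity is identically 1 and carries no information) and the model
refitted per replicate. The plain bootstrap mean and sd are reported per
effect, together with the 2θ̂ − mean bias-corrected mean; n = 10,000 by
default.

**PERMANOVA.** Sequential (Type I) partitioning of squared distances in the
order richness, drought, invasion, via the Gower-centered matrix projected
on the nested column spaces of the cumulative design matrices. Factors are
numeric covariates by default (matching the 0/1/2 codings), optionally
categorical. p-values permute pot labels; an exhaustive mode enumerates all
permutations for tiny n. The single-factor categorical case on Euclidean
distances of a 1-D variable reproduces the one-way ANOVA F exactly; factor
plus residual R² always sums to 1.

**Mantel tests** (community–community, community–multifunctionality) use
Spearman rank correlation over corresponding off-diagonal entries with
simultaneous row/column permutation of one matrix (scikit-bio backend);
similarity matrices are converted to distances (1 − S), which leaves the
correlation and its significance unchanged when applied to both sides.

**Taxa-removal contribution.** The contribution of a taxon set (species, or
families aggregated at Order rank) is the baseline correlation — over the
aspect's pairs — between community similarity and multifunctional
similarity, minus the same correlation after zeroing the set out of the
abundance table (relative abundances renormalize implicitly). A larger drop
means a larger contribution. The statistic is deterministic; removal sets
that empty a pot's community are rejected.

## Synthetic data

Two generators, both fully seeded.

**Mechanistic (`generate_experiment`).** Effects are injected on latent
community states that both abundances and functions load on, guaranteeing
the mediation structure the path model assumes. Plant biomasses are
lognormal with species-specific means; drought/invasion displace species
differentially (deterministic per species × treatment) and inflate the
within-group noise; richness shrinks noise by 1/(1 + 0.5·log2 r). Faunal
abundances respond to the plant relative-abundance profile through an
affinity matrix plus direct disturbance displacement and noise; the
disturbance noise inflation for fauna (1.5 per level) is ten times the
plant value (0.15), encoding that disturbances destabilize fauna much more
than plants. The 14 functions are linear combinations of community
summaries plus treatment displacement and noise. Faunal "counts" are kept
continuous (lognormal) so the zero-noise limit is exact. Two channels make
richness stabilizing: the noise shrinkage, and the purely combinatorial one
— assemblages at higher richness overlap more in species, so their
profiles are more alike, exactly as in the real design.

Default effect sizes were fixed once, during generator design, at the point
where the intended channel dominates: the displacement terms also
*concentrate* communities (suppressing sensitive taxa raises dominance,
which can raise within-group similarity), and with large fauna displacement
this dominance channel competed with the injected destabilization. With the
defaults (fauna displacement 0.25/level, fauna noise inflation 1.5/level),
all six qualitative sign checks (richness → plant +, richness total on
multifunctionality +, drought/invasion → both faunas −) were expressed in
30/30 seeds.

The generator emulates the statistical structure only: no plant growth or
population dynamics, no temporal axis (temporal stability aspects are out
of scope), no real phylogenies (random bifurcating trees with exponential
branch lengths), and function variables in arbitrary units. Passing tests
therefore demonstrate that the estimator recovers effects *of the assumed
mediation structure*; they do not validate that structure against real
ecosystems.

One property worth flagging: mean *multifunctional* similarity is not
monotone in the raw noise scale, because the V′ transform divides by the
noise-inflated standard deviation, compensating the added pairwise scatter.
The monotonicity of "more noise → less invariability" is asserted on the
community (UniFrac) matrices, where it holds strictly.

**Pair-calibrated (`simulate_path_matrices`).** For parameter-recovery and
calibration studies, similarity responses are drawn directly from the
recursive structural equations on the aspect's (empirically standardized)
pair covariates, with residual variances chosen to give unit total
variance, then mapped affinely into [0, 1] (standardized coefficients are
invariant to affine maps) and stored in valid similarity matrices. Matrix
cells outside the aspect's pair set are filled with i.i.d. draws on the
same marginal scale — necessary so that the permutation null resamples
values with the data's distribution. Injected coefficients are exact
targets: at the 1476-pair design, the mean fitted coefficient over 10
replicates sits within ±0.05 of every target (single-replicate estimates
carry ~0.02–0.026 sampling sd per coefficient, which is estimator noise,
not bias).

## Numerical and degenerate-input choices

* Sample (n−1) standard deviations throughout.
* Constant variables, singular parent blocks, non-positive-definite
  covariance matrices and richness levels exceeding the species pool raise
  typed errors naming the offender.
* Similarity matrices validate symmetry (1e-8), unit diagonal and [0,1]
  range on every construction; tiny negative round-off is clipped.
* Permutation and bootstrap draws use `numpy.random.Generator` seeded
  explicitly; every randomized API takes a seed, and derived seeds stay
  below 2³¹.
* Problem sizes in the test suite and acceptance script: oracle checks on
  ≤6-leaf trees and n = 5 enumerations; recovery and calibration on the
  full 270-pot / 1476-pair design with 199–1000 permutations, 500 null
  simulations, 10 recovery replicates, 20 qualitative replicates — sizes
  chosen to make Monte-Carlo error small relative to the tolerances while
  keeping a full run in minutes.

## Known limitations

* Observed-variable recursive models only: no latent variables, no cyclic
  paths, no missing-data estimation, and χ²/RMSEA inherit the usual
  caveat that pair observations sharing pots are not independent — we use
  them as descriptive fit indices, with significance delegated to the
  permutation and bootstrap machinery.
* The default edge set encodes the cascade plant → fauna →
  multifunctionality; litter ↔ soil fauna links are deliberately absent
  (df = 1) and any variant is a configuration change.
* One-way aspects only; no temporal stability or recovery.
* The taxa-removal contribution depends on the declared drop-in-correlation
  rule; other attribution rules would give different percentages.
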