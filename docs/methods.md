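# Methods

## Superimposition

Shapes are the equivalence classes of landmark configurations under
translation, scale and rotation. GPA iterates: center each configuration,
scale to unit centroid size, rotate onto the current consensus with the
2-D SVD orthogonal Procrustes solution constrained to det +1 (reflections
are excluded because left/right identity is anatomically meaningful),
re-estimate the consensus as the normalized mean, and stop when the RMS
consensus change falls below 1e-8 (max 100 iterations; non-convergence is
flagged, not fatal). The converged solution is defined only up to one
global rotation, so the package canonicalizes orientation by rotating
everything to put the consensus' first off-center landmark on the +x axis;
aligned coordinates are then exactly invariant to nuisance transforms of
the inputs, which the tests exploit.

**Sliding semilandmarks.** Semilandmarks carry information only
perpendicular to their curve, so each is allowed to move along the chord
between its declared neighbours. Per configuration the slider
displacements t minimize (v + U t)ᵀ E (v + U t), where v is the deviation
from the consensus, U holds the unit chord directions, and E is either the
consensus bending-energy matrix (block-diagonal per coordinate; default)
or the identity (Procrustes-distance criterion). Sliding runs during the
first 3 GPA iterations only: along-chord drift is unpenalized by both
criteria (the bending-energy form annihilates affine fields), so
alternating sliding with consensus updates indefinitely need not settle —
a few passes followed by plain GPA is the conventional remedy, and the
pass count is a parameter. Slid points are re-projected onto the chord
direction, not constrained to the original polyline.

**Tangent projection and check.** Aligned pre-shapes live on the unit
sphere; analyses need a linear space, so shapes are orthogonally projected
onto the tangent plane at the consensus. The tangent check regresses the
tangent distance to the consensus (= sin ρ) on the Procrustes geodesic
ρ = arccos⟨x, c⟩ through the origin and reports slope and correlation;
slopes above ~0.99 mean the curvature of shape space is negligible at the
observed variation, which holds for all datasets this package targets
(within-genus variation of ants is small relative to the sphere).

## Variance decomposition and ordination

Procrustes ANOVA treats the flattened tangent coordinates as one
multivariate response and measures sums of squares as summed squared
Euclidean distances. Factors enter sequentially (Type I) as
species → site → replicate; site is nested in species by default
(`nest_site_in_species`) because sites are geographic subsets of each
species' sample. Goodall's F divides mean squares, and significance comes
from randomized residual permutation (RRPP): residuals of the reduced
model (all preceding terms) are permuted, added back to the reduced-model
fit, and the term's F recomputed; p = (#{F\* ≥ F}+1)/(n_perm+1), 999
permutations by default, seeded. The replicate factor captures *systematic*
digitization bias between first and second passes; random digitization
noise appears in the residual, which is the conventional reading of
measurement error in this design. Permutation exchangeability assumes
independent rows — replicated digitizations of one specimen are
correlated, so size-calibration experiments use one replicate per
specimen, and real analyses should read the species test with the
replicate structure in mind (or use the `mean` replicate policy, which
averages replicates per specimen before ordination and classification).

Relative warps with weighting exponent α = 0 and the uniform component
included are exactly the principal components of the tangent coordinates;
the package computes them by SVD, so full score space is isometric to
tangent space. Between-group PCA eigen-decomposes the covariance of the
*equally weighted* group means and projects all individuals; percent
variance per axis is reported both as group-mean eigenvalue share (the
number used in ordination summaries) and as share of total projected
individual variance, because the two conventions differ and published
figures rarely say which was used. Axis signs are fixed by making the
largest-magnitude loading positive; eigenvalue ties keep the
decomposition's stable order.

## Thin-plate splines

Kernel convention U(r) = r²log r² (the Bookstein convention; using
r²log r instead halves the quadratic form — the convention is fixed here
and matters only for absolute bending-energy values). Affine and
non-affine coefficients solve the bordered system [[K,Q],[Qᵀ,0]]; the
bending energy is tr(WᵀKW), zero exactly on affine maps, and equal to
1/(16π) times the integral of squared second derivatives of the map (the
test suite verifies this against quadrature). Deformation grids sample the
determinant of the analytic Jacobian at cell centers; grids for ordination
axes warp the consensus to consensus + c·axis with c spanning the observed
score range, matching how such figures are conventionally bracketed.
Collinear or duplicate reference landmarks make the system singular and
raise immediately.

## Discrimination

CVA solves the generalized eigenproblem B v = λ W v with B the
(size-weighted) between-group and W the pooled within-group covariance of
the leading warp scores. Because W must be nonsingular, scores are
truncated to the leading columns explaining 99% of variance, bounded by
n − g − 1 (`retain` accepts an integer, a fraction, or `"all"`); a
singular W after truncation raises with advice to retain fewer. Percent
per canonical axis is its eigenvalue share. Jackknifed classification
refits the full CVA without each individual (the cheaper
group-means-only variant is available as `refit="means"`), projects it,
and assigns it to the nearest group mean in canonical space — Euclidean
there equals Mahalanobis in the original space under the CVA metric.
Pairwise PERMANOVA computes the two-group pseudo-F from the Euclidean
distance matrix via the Gower identity (the coordinate form is kept as an
independent cross-check), with 9,999 seeded label permutations and
Bonferroni correction across pairs. All digitized configurations,
replicates included, enter by default, matching how replicated datasets
are usually analysed; the `mean` policy is the alternative.

## Barcode clustering

Uncorrected p-distances use pairwise deletion: only sites that are
unambiguous A/C/G/T in both sequences count, so N, gaps, and all other
IUPAC ambiguity codes are missing data (gaps-as-differences is a
configurable alternative the package deliberately does not default to,
since indel treatment in the underlying protocols is rarely stated).
Objective clustering at threshold t is the connected components of the
graph joining pairs with d ≤ t (inclusive), identical to cutting the
single-linkage dendrogram at t — an identity the tests assert. Pairs with
no comparable sites contribute no edge and emit a warning; the merge
profile requires a complete matrix. Merge heights are reported as
percentages to one decimal in exported dendrograms.

## Synthetic data

The shape generator emulates a replicated digitization study:
configuration = nuisance ∘ (template + species field + site field +
N(0, σ²) per landmark + N(0, σ_rep²) per replicate). Species and site
fields are drawn once per run as thin-plate splines through a few random
anchor displacements and rescaled to a target RMS — smooth,
low-bending-energy deformations, because white-noise mean offsets would
make discrimination unrealistically easy. The default template is a
33-point ant-head scheme (13 fixed + two 10-point lateral curves) so
slider logic is exercised. Defaults (template units; the template has unit
centroid size): species effect 0.05, site effect 0.015, specimen σ 0.01,
digitization σ_rep 0.003, rotation uniform on [0, 2π), scale 0.75–1.25,
translation ±0.5 — i.e., mean species differences five times the
within-species landmark scatter, and digitization error a third of it,
which is the regime where classification is good but imperfect, as in real
within-genus data. What the generator does *not* emulate: allometry,
correlated (anisotropic) landmark noise, curve resampling artefacts, and
missing landmarks — so passing tests certify the statistical machinery,
not robustness to those real-data features.

The sequence generator realizes a target between-group divergence matrix
by neighbor-joining it into a tree and assigning every edge a disjoint
block of ⌈ℓ·L⌉ sites mutated (to one shared non-ancestral base) in all
groups on one side, so ancestor distances equal tree path lengths exactly
up to rounding; matrices violating the triangle inequality produce
negative NJ branches and raise. Individuals receive within/2 extra
mutations from their group ancestor, and targets are pre-shrunk by the
within rate so realized between-group *means* match. Mutations are placed
uniformly without back-mutation correction — targets are uncorrected
p-distances, so this is exact by construction up to sampling. Note the
distinction between mean divergence (what the generator targets) and
single-linkage split height (≈ ancestor divergence, one within-rate
lower): study-style datasets that should split at a stated threshold set
the target to threshold + within.

## Problem sizes and numerics

The synthetic study mirrors a realistic imaging campaign: 256
configurations × 33 landmarks for shapes and 108 × 313 bp for barcodes;
calibration experiments use 500–1,000 null datasets of n = 40 with a
6-landmark template and 199 permutations each, sizes at which the full
suite and the acceptance script each run in well under a minute.
Convergence: GPA tol 1e-8 on consensus RMS change, plus a rotation-only
polish loop to ~1e-14 so the stored consensus equals the mean of the
aligned shapes to machine precision. Rank decisions use relative singular
value thresholds (1e-9–1e-10); negative round-off bending energies are
clipped at zero; permutation p-value comparisons use a 1e-12 slack so ties
count as exceedances. Degenerate inputs (zero centroid size, collinear TPS
references, constant factors, singleton groups, empty bounding boxes)
raise named errors rather than propagating NaNs.

## Known limitations

2-D landmarks only; no missing-landmark estimation; no α ≠ 0 relative-warp
weighting; no phylogenetic correction in the ANOVA; no model-corrected
(K2P etc.) distances or coalescent delimitation (GMYC/PTP) — barcode input
must be pre-aligned. The jackknife refit recomputes the truncation rank
per left-out specimen, so reported accuracies can differ by a configuration
or two from implementations that freeze the rank.
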