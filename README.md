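# cryptomorph

Integrative delimitation of cryptic species from two complementary data
streams: **2-D geometric morphometrics** of landmark configurations
digitized on specimen images, and **objective clustering of DNA barcodes**.
It is written for taxonomists and evolutionary biologists who have
(i) TPS landmark files with slider definitions and a specimen label table,
and/or (ii) an aligned COI barcode matrix, and who want the full analysis
stack — superimposition through classification — as reproducible,
scriptable Python instead of a chain of GUI tools.

## What it computes

**Morphometrics.** Configurations of *k* landmarks are superimposed by
generalized Procrustes analysis (GPA): centering, scaling to unit centroid
size CS = √Σᵢ‖xᵢ − x̄‖², and rotation onto the iteratively re-estimated
consensus by the closed-form 2-D orthogonal Procrustes solution (det +1 —
no reflections). Semilandmarks declared in a sliders file are slid along
the chord of their neighbours to minimize either the thin-plate-spline
bending energy against the consensus (default) or the Procrustes distance.
Aligned shapes are projected onto the tangent space at the consensus, and
a tangent check regresses tangent on Procrustes distances (slopes ≈ 1
certify the linearization). On tangent coordinates the package provides:

- **Procrustes ANOVA** (Goodall's F): sequential sums of squares for
  species → site (nested in species) → replicate, with p-values from
  randomized residual permutation (RRPP),
  F = (SS_f/df_f)/(SS_res/df_res), p = (#{F\* ≥ F}+1)/(n_perm+1).
- **Relative warps** (principal components of tangent coordinates, α = 0,
  uniform component included) and **between-group PCA** (eigen-analysis of
  the equally-weighted group-mean covariance, individuals projected on).
- **Thin-plate spline deformation grids**: the TPS with kernel
  U(r) = r²log r² interpolating the consensus onto consensus + c·axis, its
  bending energy tr(WᵀKW), and the determinant of its analytic Jacobian
  sampled on a grid (expansion factors: >1 expansion, <1 contraction).
- **CVA** (generalized eigenproblem of between- vs pooled within-group
  covariance on variance-truncated warp scores), **jackknifed
  classification** (leave-one-out refit, nearest group mean in canonical
  space, confusion matrix) and **pairwise PERMANOVA** (pseudo-F on
  Euclidean distances, 9,999 permutations, Bonferroni correction).

**Barcodes.** Uncorrected p-distances (pairwise deletion of sites that are
not unambiguous A/C/G/T in both sequences), objective clustering as
connected components of the ≤-threshold graph (the single-linkage cut),
and the full single-linkage merge profile exported as a Newick dendrogram.

**Synthetic data.** A generator plants known ground truth for both
streams — smooth per-species/site mean-shape fields, specimen and
digitization noise, nuisance rotation/translation/scale; and sequence sets
realizing a target between-group divergence matrix exactly (tree-consistent
targets via neighbor joining into disjoint mutated site blocks) — so every
stage is testable at desk scale.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (seed 1) and narrate what they find:

```sh
python analysis/01_simulate_study.py
python analysis/02_superimpose.py
python analysis/03_shape_variation.py
python analysis/04_discriminate.py
python analysis/05_barcode_clustering.py
```

Output (abridged):

```
GPA converged in 6 iterations (consensus RMS change 1.75e-09)
tangent approximation: slope = 0.9910, correlation = 0.999980
Procrustes ANOVA (Goodall's F, sequential SS, site nested in species):
source        df    ss      percent_ss   F         p
species        7    6.7683  70.6519      102.7068  0.001
site           8    0.5594   5.8391        7.4273  0.001
replicate_id   1    0.0021   0.0221        0.2251  1.000
between-group PCA: top five axes summarize 98.6% of group-mean variation
CVA on the leading 38 warp scores: CV1+CV2 explain 72.2% of among-group variance
jackknifed classification accuracy: 96.5% (247 of 256 correctly assigned)
pairwise PERMANOVA (9,999 permutations, Bonferroni): 28/28 pairs significant
threshold 4%: 8 clusters
deepest ingroup split (jspA vs rest): 10.5%
4% partition vs planted units: Rand agreement 1.000
```

Reading: species differences dominate shape variation (70.7% of SS,
p = 0.001), site adds a small nested effect, and digitization replicates
contribute nothing systematic; the planted eight species are almost
perfectly recoverable from head shape alone, and barcode clustering at the
4% threshold reproduces the planted units exactly, with the deepest
ingroup split at 10.5% and outgroups ≥ 18.5% away.

The same analyses run on real inputs through one YAML config
(`cryptomorph run-all --config study.yaml`) or the per-stage subcommands
(`simulate`, `gpa`, `anova`, `ordinate`, `cva`, `permanova`, `barcode`).

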