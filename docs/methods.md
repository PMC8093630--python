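# Methods

This note documents the models and procedures implemented in `pcrad`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data tests do and do not demonstrate.

## Problem setting

A cohort of breast-cancer patients receives neoadjuvant chemotherapy (NAC);
the binary endpoint is pathologic complete response (pCR) at surgery. Before
NAC each subject has DCE-MRI (a dynamic post-contrast acquisition and a
subtracted image), diffusion MRI (ADC), FDG-PET (SUVmax), BI-RADS-style
lesion descriptors (Shape, Margin, internal enhancement, kinetic curve type,
lesion type), tumor grade and biopsy histology (Ki67, ER, PgR, HER2). The
question is whether radiomic descriptors of the lesion add predictive value
over the clinical/histological covariates.

## Image preprocessing and the five radiomic features

Processing order is **normalize → resample → discretize**, the order used by
standard radiomics extractors. Normalization forces the whole-volume mean/sd
to 0/100 (an ROI-only switch exists, off by default, because which region fed
the normalization statistics is rarely reported and whole-volume is the common
extractor default). Resampling is to isotropic 0.90 mm cubes with cubic
b-splines for intensities and nearest-neighbour for the mask — b-splines on a
binary mask would produce non-binary values. Discretization uses a fixed bin
count of 8 over the masked intensity range, with the maximum mapped to the
top bin; a constant ROI maps to level 1 and is flagged degenerate.

- **Sphericity (F1)** uses a triangle mesh from marching cubes at the 0.5
  iso-level of the zero-padded mask, with volume from the signed-tetrahedron
  sum and area from the mesh triangles. A raw marching-cubes surface of a
  voxelized shape carries staircase artifacts that inflate the area by ~8–9%
  (a digital ball of radius 20 voxels plateaus near 0.92 rather than 1), so
  the mesh is regularized with 20 iterations of Taubin smoothing
  (λ = 0.5, ν = −0.53), which is volume-preserving to first order. Thin
  structures can collapse under smoothing; if the smoothed mesh loses more
  than half the raw mesh volume, the raw mesh is used instead (this keeps a
  1×1×20-voxel rod and single-voxel masks valid). With this choice the
  digital ball gives 0.9994 and the rod 0.396.
- **Kurtosis (F2)** is the population moment ratio m₄/m₂² on the continuous
  (not discretized) masked intensities — Pearson convention, normal = 3, no
  bias correction.
- **GLDM dependence variance (F3)**: a voxel's dependence is 1 (the centre
  counts, configurable) plus the number of in-mask Chebyshev-distance-1
  neighbours within a level tolerance α (default 0). The feature is the
  variance of dependence under the normalized dependence matrix, which equals
  the population variance of per-voxel dependences.
- **GLRLM long-run high-gray-level emphasis (F4)**: maximal runs of equal
  level along each of the 13 unique 3D directions, masked voxels only, runs
  broken at the mask boundary; per direction (1/Nr) Σ i²j², then the
  unweighted mean over directions (the common extractor default; no weighting
  scheme is standard).
- **GLSZM high-gray-level zone emphasis (F5)**: zones are 26-connected
  components of equal level inside the mask; (1/Nz) Σ i² over zones.

F2, F4, F5 are computed on the dynamic channel and F1, F3 on the subtracted
channel. Every texture statistic is checked for exact equality against
independent brute-force loop/flood-fill oracles on random ≤5×5×5 ROIs; mesh
sphericity has no small-ROI equality oracle, so it is validated through the
sphere limit, scale invariance, and shape orderings instead.

## Univariate statistics

Continuous covariates: Welch two-sample t-test with Welch–Satterthwaite
degrees of freedom (kept non-integer), available from raw samples or from
printed (n, mean, sd) summaries so published tables can be recomputed without
subject-level data. Categorical covariates: exact Fisher test; for r×c tables
the Freeman–Halton extension is computed by full enumeration of tables with
the observed margins — the largest table in scope is 3×2 with N = 60, for
which enumeration is trivial — with the two-sided p defined as the total
probability of tables no more probable than the observed one (relative slack
1e-7, the convention of the common statistical environments, which the
recomputed published p-values confirm). Spearman correlations use average
ranks for ties.

## Feature reduction

L1-penalized logistic regression minimizing
`(1/n)·NLL + λ·Σ|βⱼ|` (intercept unpenalized) on standardized columns
(population-sd convention, recorded in the scaling object). The solver is
cyclic coordinate descent on the IRLS quadratic approximation with warm
starts along a decreasing grid of 100 log-spaced penalties from the analytic
λ_max = maxⱼ |(1/n)·Xⱼᵀ(y − ȳ)| down to 10⁻³·λ_max, converged when the
largest coefficient change falls below 10⁻⁷. Solutions satisfy the KKT
conditions to ~10⁻⁹ and match R's glmnet to ~10⁻⁷ on shared grids.

λ is selected by minimum mean LOOCV held-out binomial deviance (no
one-standard-error rule). Each fold refits the whole path on n−1 subjects
with fold-level restandardization; fold/penalty solves are warm-started from
the full-data path, which changes only the iteration count, not the optimum
(the problem is convex). Features with nonzero coefficients at λ_min survive.

## Synthetic cohorts and phantoms

`generate_cohort` draws continuous covariates group-conditionally Gaussian
and categorical covariates group-conditionally multinomial; the default
specification uses the published per-group means/sds and category frequencies
of the 20-responder / 40-non-responder cohort. Radiomic feature moments are
not published; the defaults plant moderate group differences whose signs
follow the reported direction of association (F1, F2 higher in responders;
F3, F4 lower; F5 near-neutral). Continuous covariates are independent by
default — the published correlation screen found the continuous covariates
effectively independent — and Gaussian even where the real quantity is
bounded (percentages); an optional truncation clamp and an optional
correlation matrix exist, both off by default. One integer seed drives a
hierarchical stream, so cohorts and phantoms are independently reproducible.

With a planted `OutcomeModel`, covariates are drawn from pooled
mixture-moment marginals and the outcome from a Bernoulli logistic model on
the standardized dummy-encoded design; the planted coefficients are
recoverable by an unpenalized logistic refit (tested at n = 2000).

Phantoms are ellipsoids (centre-of-voxel inclusion test) on a noisy constant
background, with constant, smooth-gradient or correlated-noise lesion
textures (Gaussian-filtered white noise with a stated correlation length,
rescaled to a target sd). The "subtracted" channel is the dynamic minus the
baseline plus independent noise. These phantoms exercise geometry and texture
monotonicity (longer correlation length ⇒ larger long-run emphasis; sphere ⇒
higher sphericity than rod); they do not emulate pharmacokinetic enhancement,
partial volume, bias fields or acquisition artifacts, so passing tests show
the machinery is correct, not that the features are biologically validated.

## Model search and AUC inference

Subsets are enumerated at the original-covariate level — a categorical's
dummy columns enter and leave together — because "18 covariates → 2¹⁸
subsets" only makes sense at that granularity. The empty subset is excluded.
Classifiers: logistic regression (in-package damped Newton solver,
oracle-tested against scikit-learn per fold), linear-kernel SVR on the 0/1
outcome (scikit-learn), and random forest (scikit-learn), with SVR cost and
RF tree count tuned once on the full-group LOOCV model (cost grid 2⁻⁵…2⁵ odd
powers, trees {100, 250, 500, 1000}, ties to the smallest) and frozen.

Every subset is scored by the mean of two pooled out-of-fold AUCs:
leave-one-out and one seeded unstratified partition into folds of size two.
Standardization is refitted on training folds only. DeLong confidence
intervals and the Mason–Graham test against AUC = 0.5 are computed on the
pooled leave-one-out scores (the only scheme giving exactly one score per
subject); the Mason–Graham p uses the exact Mann–Whitney null when
n_pos·n_neg ≤ 10⁴ and the scores are tie-free, and the tie-corrected normal
approximation otherwise. All p-values from one search run are
Benjamini–Hochberg adjusted together.

Two numerical facts worth knowing:

- Pooled cross-validated scores of a *null* model are pessimistic (mean AUC
  well below 0.5 at n = 40–60): excluding a subject from training
  anti-predicts it. The tests assert the direction of this bias rather than a
  0.5 calibration, which holds only for outcome-independent scores fed
  directly to the AUC.
- Quasi-separation is common with ≥10 design columns on 60 subjects. The
  Newton solver caps iterations, stops when the objective stalls, and flags
  such fits; flagged fits are excluded from coefficient aggregation, and CV
  folds are warm-started from a lightly ridge-stabilized full-data fit purely
  to cut iteration counts.

Reports rank models by mean AUC (ties: fewer covariates, then lexicographic),
keep the best six, compute per-covariate best-6 inclusion frequencies, and
aggregate full-data logistic coefficients per design column as
`m_j = Σᵢ m_ij σ_ij⁻² / Σᵢ σ_ij⁻¹` — the published weighting, implemented
literally; a configuration switch provides the textbook inverse-variance
variant `Σ m/σ² / Σ 1/σ²`. Beyond a subset cap (default 2¹⁴) a seeded uniform
sample of subsets is evaluated and the report flags truncation.

## Pipeline

The CLI stages (simulate, extract, table1, reduce, search, report) are thin
wrappers over the library. Manifests record stage, parameters, seed and
package version — no timestamps — so identical configurations yield
byte-identical artifacts.

## Problem sizes used in validation

The validation suite uses the cohort's own scale wherever the analysis is
defined by it (n = 60, 20/40 split, LOO = 60 folds), 50 seeds at n = 200 for
penalized-selection recovery, 25 seeds for end-to-end planted-signal
recovery with the All group capped at 2¹⁰ subsets per run, 500 simulations
for the significance-test null calibration, and 100 random ROIs for the
texture oracles.

## Known limitations

- Only the five selected features are implemented, not a full extractor
  catalogue; no filtered-image (wavelet/LoG) variants.
- Mesh sphericity depends on the smoothing choice described above; values for
  very thin structures come from the raw mesh and carry staircase bias.
- The synthetic cohort matches group-conditional marginals, not the joint
  distribution of the real cohort; headline AUCs on synthetic data are not
  comparable to values obtained on patient images.
- r×c Fisher enumeration is exponential in principle and intended for the
  small tables of cohort characteristics, not for large sparse tables.
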