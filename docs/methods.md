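# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## The screen model

Counts are modeled per unit with a log-link Poisson mean and a free
variance multiplier (quasi-Poisson): `Var(Y) = phi * E(Y)`. Fitting is
iteratively reweighted least squares (IRLS) to a relative deviance
tolerance of 1e-8 (max 100 iterations), with the Pearson dispersion
`phi = chi^2 / df_resid`. The screen fits all units against one shared
design matrix, so IRLS is vectorized across units (batched
weighted-normal-equation solves); single-unit fits agree with the
batched path to 1e-6 and both agree with an independent GLM
implementation (statsmodels) to the same tolerance.

Model terms: intercept; sex dummy; orthonormal degree-1/degree-2
polynomials of the ordinal timepoint codes 1–4 (0, 2.5, 6, 22 h — the
quadratic captures the mating hump at 2.5/6 h); block as a single
numeric covariate 1–6 (dummy coding available via `block_as_factor`);
and for the bonding model a mate dummy plus its products with sex and
both time polynomials. An intercept is always included: the printed
model formulas without one would make a count GLM degenerate, and the
nested F comparison is unaffected because both models share it. The F
statistic is basis-invariant (raw `{T, T^2}` versus orthogonal
polynomials give identical F), which the suite asserts to 1e-6.

Degenerate inputs: an all-zero response is returned as a flagged
saturated fit (deviance 0, dispersion 0, F = 0) instead of driving the
intercept to −∞; collinear added columns (rank difference 0) raise.

## Permutation calibration

The null distribution of F comes from re-labeling which pairs are
"mates". One shuffle produces one relabeled design applied to all
units, so permutation indices are shared across units within a
replicate, and the p-value uses the add-one estimator
`p = (1 + #{F_perm >= F_obs}) / (1 + N)` — strictly positive, with
floor 1/10001 ≈ 0.0001 at the conventional N = 10,000.

The default shuffling unit is the pair (both animals keep their sex,
timepoint and block and always share a label), stratified by timepoint
**and block**. Stratifying by timepoint alone is offered
(`scheme="pair_timepoint"`) but is not the default for a concrete
reason found during development: block effects are a shared, imperfectly
modeled factor (the linear block term underfits arbitrary day-to-day
variation common to every unit), and label swaps that cross blocks then
break exchangeability — the null screen becomes measurably
non-uniform. Swapping labels only within a testing day preserves the
design's balance exactly and restores uniform null p-values, which the
acceptance suite verifies by Kolmogorov–Smirnov test on a 500-unit null
simulation. Unrestricted pair shuffling (`"pair"`) and response-row
shuffling (`"rows"`) are available for comparison; the exhaustive
mini-design test (6 pairs, all 20 balanced relabelings enumerated
against an independent oracle) uses `"pair"`.

FDR control is Benjamini–Hochberg by default with the screen convention
q < 0.1; Storey q-values (fixed lambda = 0.5) are available because
some analyses of this kind cite the q-value method instead. Behavioral
tests use q < 0.05.

## Exclusive ROI selection

The atlas is a rooted structure tree; "anatomical overlap" is exactly
the ancestor/descendant relation (siblings never overlap). Selection is
greedy by F descending: accept a unit iff it is unrelated to every
accepted unit. Ties on F go to the deeper (more localized) node, then
to lexicographic acronym order, making the output deterministic and
independent of input row order. The suite checks this against an
independent fixed-point re-implementation on random trees, including
tie-heavy instances.

## Clustering, MDS, connectome test

Distances between chosen ROIs are Euclidean over per-unit z-scored
counts (z-scoring keeps high-count regions from dominating; a raw-count
path is a config choice away by skipping `zscore_units`). Ward linkage
is ward.D2 (scipy's `ward` on a distance matrix; heights on the
distance scale), verified against an O(n^3) Lance–Williams oracle for
n ≤ 12. The cluster count k is a parameter (default 8, a judgment call
in the emulated study, not optimized automatically). MDS is non-metric
(Kruskal), initialized from classical MDS for determinism, reporting
stress-1.

The connectome test maps each chosen ROI to itself in the connectivity
matrix or, when it is a subregion, to its nearest ancestor present
(e.g. a posterior-BST subnucleus borrows the BST row). Cluster density
is the mean of off-diagonal entries among members, both directions;
the overall statistic is the unweighted mean over clusters (weighting
by cluster size is a plausible alternative the emulated analysis does
not specify). The null shuffles entire origin rows, excludes positional
diagonal cells after shuffling, and uses the same add-one p estimator.
A cluster subset argument supports excluding a minimally-correlated
residual cluster from the test, as the emulated study did.

## CCA and Wilk's lambda

Classical CCA on z-scored variable sets via SVD of the whitened
cross-covariance, with rank handled by singular-value thresholding
(dimensions beyond either set's rank are dropped with a warning; no
regularization by default, since the intended regime n ≈ 190 with
~70 + ~10 variables is full-rank — a ridge would be the natural
extension for wider sets). Scores are unit-variance; each factor is
oriented so its largest-magnitude behavior loading is positive, a
convention that makes CC1 read as "more mating → higher score".
Sequential Wilk's tests use `Lambda_k = prod_{i>=k}(1 - rho_i^2)` with
Rao's F approximation; the first-factor null p-values are uniform in
simulation (KS-checked over 500 replicates). Animals at the 0 h
timepoint have observed zeros, not missing values, for interaction
behaviors — they were watched and did not interact.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design exactly at its defaults: per
timepoint, 12 mate pairs (F+M) and 12 sibling pairs (half F–F, half
M–M), 192 animals, six testing blocks balanced across partner types
(adjacent mate/sibling pairs share a block, mirroring two-pairs-per-day
testing), and the study's bookkeeping after exclusions (189 IEG /
190 behavior of 192). The design table is fully deterministic given the
pair count.

Counts are gamma-Poisson (negative binomial with `Var = phi * mu`,
default phi = 2.5): quasi-likelihood is an estimating assumption, not a
sampling distribution, and the gamma-Poisson is the standard generative
model matching its mean–variance relation. The log-mean combines a
per-unit baseline (normal, sd 0.5 around log-mean 4 — c-Fos counts in
the hundreds), a small sex effect, a hump-shaped time profile, i.i.d.
normal block effects (sd 0.1; the emulated analysis adjusts for block
but never quantifies it), planted partner effects (default 68 units at
log-effect 0.7 — chosen for testability, as no count-scale effect sizes
are published), a per-animal cluster latent correlating units that share
a planted cluster, and pair-level coupling. Atlas units are leaves of a
generated structure tree; internal structures carry the sum of their
leaf descendants, so planted leaf effects propagate to ancestors and the
exclusive-selection step faces realistic nested hits.

Coupling multiplies the count mean of designated units by `z^gamma`
(mate pairs, mating timepoints), where `z ~ lognormal(0, 1)` is shared
by both pair members and also drives the ejaculation count
(`Poisson(6z)` per mating-window hour — a rate high enough that the
observed count is a reliable readout of the latent). With gamma = 1 the
count mean is linear in `z`, so a linear partial correlation on the
latent (or its ejaculation readout) genuinely removes the planted
coordination; coupling of the form `exp(gamma * z)` was rejected
because the e^lognormal tail makes the mean so nonlinear in `z` that no
linear control could ever abolish it.

What the generator does **not** emulate: imaging, registration or
segmentation artifacts; spatial autocorrelation between neighboring
units (voxel mode is just a wider matrix of independent columns);
sex-specific effect sizes; non-stationary behavior within the focal
window; and any USV acoustics or video. Passing tests therefore show
that the statistics behave correctly under the assumed generative
model — they do not show robustness to registration error or spatially
structured noise.

## Problem sizes used by the test and acceptance runs

Simulations are sized so the full suite runs comfortably on one CPU:
null calibration uses 500 units x 200 permutations x 96 animals;
FDR/power uses 20 replicates of 100 units (20% planted at log-effect
0.7) x 200 permutations; coordination recovery uses 20 replicates of
12 units x 24 mate pairs with nuisance effects held flat (so coupling
is the only within-pair dependence being tested); CCA recovery uses 20
replicates at n = 1000; the end-to-end run uses the full default
design (192 animals, 800 leaf units, 68 planted, 200 screen
permutations, 10,000 connectivity permutations). Oracle-equivalence
checks run 100+ random instances each. Permutation counts below the
conventional 10,000 only coarsen p-value resolution; they do not bias
the estimators.

## Known limitations

- The permutation screen assumes pairs are exchangeable within a
  stratum; systematic confounds between partner type and unmodeled
  covariates would evade it.
- Storey q-values use a fixed lambda rather than the smoother fit of
  the reference implementation; for the screen's p-value grids the BH
  default is the safer choice.
- Non-metric MDS can stop in local minima; the classical-MDS
  initialization makes results deterministic, not globally optimal.
- The ESD outlier screen presumes approximate normality of whole-brain
  totals; heavy-tailed totals would inflate its false-positive rate.
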