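# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish about real recordings.

## Object space

The object space is the image of an activation matrix under centering,
PCA whitening to `k` components (default 25) and an orthonormal ICA rotation
maximizing non-Gaussianity (FastICA, log-cosh contrast, symmetric
decorrelation; the returned rotation is polar-projected onto the orthogonal
group so `R Rᵀ = I` holds to machine precision). `explained_variance_fraction`
is the top-`k` share of total centered variance. ICA leaves axis sign and
order unidentified; we fix sign by requiring positive skewness of each
axis's image coordinates, which makes pole identity reproducible across
seeds, and leave order as returned (tests align by best sign/permutation
match).

Representative-image selection ranks images by the angle (0–180°) between
their coordinate vector and an axis; ties break by ascending image id and
zero-norm coordinate rows are excluded with a warning. The chance-duplicate
simulation draws groups without replacement by rejection resampling of any
group with an internal collision, which is exact; its analytic counterpart
(`n_pool · P(Binomial(n_groups, size/pool) ≥ 2)`) is used as the test
oracle. Mutual information between axis pairs uses equal-count (quantile)
binning, 16 bins, reported in bits; the estimator is configurable because
the choice is not canonical.

## Block design and the Fourier pipeline

The default scan is seventeen 24-s blocks (408 s) sampled at 2-s volumes
(204 volumes): two lead-in positive blocks, a contiguous twelve-block
negative/positive alternation (six 48-s cycles — the analysis window), then
control, gray, gray. This keeps eight positive and six negative blocks and
places the control block immediately before a gray block, whose combined
48-s window supplies the one-cycle control coefficient. The exact layout of
the non-analysis blocks is a package choice; only the analysis-window and
control-window structure matters to any computation.

The DFT convention is `c = (2/N) Σ x[n] e^{−2πikn/N}`, so a cosine of
amplitude A at the analysis frequency returns magnitude A; the sampled
square wave returns `1/(6 sin(π/24))`, the discrete analogue of the
continuous `4A/π`. Hemodynamics are modeled as a pure phase lag (default
4 s), not an HRF convolution: the pipeline uses only the phase of the
fundamental, which a delay captures exactly.

The sign rule needs to know which phase-histogram peak is the
negative-preferring population. We smooth the circular phase density with a
wrapped Gaussian kernel (bandwidth 0.25 rad), take the two largest modes and
call the one at the larger raw phase in [0, 2π) the negative peak: any
physiological delay is under a quarter cycle, so the positive peak lies
below π and the antipodal negative peak to its right. A rule based on which
mode is "later" circularly is undefined at exactly π separation — the
generic case — and was rejected for that reason. If the histogram is
effectively unimodal (second mode under 20% of the first) the reference
falls back, with a warning, to the global circular mean plus π/2. A phase
exactly π/2 from the reference counts as positive (measure-zero tie, fixed
for determinism).

Control normalization averages the absolute control magnitudes of all
significant voxels within Euclidean distance 5 (voxel units) of the target
voxel — a guard against small single-voxel denominators; the numerator
stays single-voxel. Voxel significance is a paired two-tailed
t-test of control-block vs gray-block mean signal across scans (threshold
0.001, uncorrected); the degenerate noiseless limits resolve to p = 0
(nonzero mean difference) or p = 1. The t-test consumes raw block means;
a GLM-beta variant would slot into the same interface.

Gridding averages per-vertex 25-D values in square cells (default 2 mm) and
unit-normalizes the mean; empty and zero-norm cells are masked.

## Feature axes, selection and the noise ceiling

Axis constructors all end in unit normalization: per-image scalars are
projected as positive-pole mean minus negative-pole mean per axis
(`label_axis`, shift-invariant); group contrasts as difference of mean
coordinates. Spatial-frequency features average power-spectrum magnitude in
seven octave annuli anchored at the printed 0.18–0.36 and 1.45–2.91
cycles/degree bands (so the ladder spans 0.09–11.64; the full list is not
published and octave spacing is the natural completion); degrees-per-pixel
defaults to 11°/227 px, the stimulus size. Colorfulness is the mean over
pixels of the per-pixel standard deviation across R, G, B.

Greedy selection scores candidates by mean SCA to the cell vectors, admits
only candidates with |cos| < 0.5 to every already selected axis,
orthogonalizes the tentative set by Gram–Schmidt **in selection order** (the
natural reading; order is otherwise unstated) and picks the best summed-SCA
candidate, ties broken by input order. The optimal count maximizes the
half-split GOF, averaged over caller-supplied half-pair draws.

The naive noise ceiling (fit one half directly with the other)
underestimates the ceiling because both halves are noisy. The correction is
re-estimated by simulation rather than copied from any published curve:
planted maps are built by resampling unit vectors from the normalized sum of
the two observed halves (keeping their directional structure), perturbed at
40 noise levels with 3 replicates, and an isotonic regression of true GOF on
naive ceiling is inverted at the observed naive value, clipped at 1. Note a
regime limitation: under very heavy noise a shrunken predictor beats the
unit-norm ground truth, so "fraction of ceiling" can legitimately exceed 1;
at the moderate noise levels the synthetic defaults use it does not.

Residual features orthogonalize the cell vectors against the selected span
and pool residuals with their negations before PCA, forcing a zero-mean,
sign-symmetric decomposition. Region inversion uses the pseudo-inverse and
reports the condition number, warning above 1e6.

## Parcellation and dimensionality

The GMM is EM with diagonal covariances, covariance regularization 1e-5 on
the diagonal, k-means++ initialization (the initializer is unstated
upstream; k-means++ is the standard robust choice), convergence tolerance
1e-6, best of `n_restarts` re-initializations (desk-scale default 20; the
full-fidelity 500 is a parameter). BIC uses `M = (2D+1)k − 1`. The k-sweep
averages BIC over repeated re-initializations per k (re-initialization, not
data resampling) and returns the argmin.

Half-split dimensionality: per iteration, each axis's scans are randomly
halved and averaged; both half maps are (optionally) row-normalized;
principal axes are fit on half 1 (centered by its own mean) and both halves
projected; the per-dimension Pearson correlation is recorded **as is** — a
negative correlation counts as non-positive, matching the "more than 99%
positive" criterion literally, with no sign alignment. Projections with
numerically zero variance (below 1e-8 of the overall projection scale)
count as undefined/non-positive; without this floor, float-level variance
in dimensions beyond the true rank correlates perfectly between identical
halves. The planted-rank simulation reconstructs the map from its top-n
principal axes and adds spatially filtered Gaussian noise (isotropic
Gaussian kernel, default width 3 mm, unit variance over cells — standing in
for the data-derived difference-map correlation structure, and
user-configurable). The reconstructed responses are analyzed without
re-normalizing rows: normalization of a rank-n reconstruction would leak
deterministic structure into higher dimensions and confound the planted
rank. Use at least ~100 split iterations: the >99%-positive criterion needs
enough resolution that a mildly positively biased noise dimension is not
accepted just because every one of a few dozen iterations came out positive.

## Topography

The autocorrelation at lag (dx, dy) is the Pearson correlation over all
co-valid cell pairs at that offset (pairwise-complete); lags with fewer
than `min_pairs` (default 10) pairs are undefined. A brute-force double
loop over cell pairs is the test oracle and agrees exactly.

The rectangle spectrum resamples the lag map bilinearly inside a centered
rotated rectangle (defaults 66 mm × 22 mm), averages across the short edge
ignoring undefined lags, mean-imputes fully undefined long-edge columns
(configurable off — whether the original projection imputed or skipped is
unstated), and keeps DFT magnitudes at integer cycles 1–5 per rectangle
length. Orientations with over half their samples undefined are flagged.
The sinusoid-fit spectrum least-squares fits
`A cos(2πf·(dx cosθ + dy sinθ)/L + φ) + c` over defined lags per
(frequency, orientation) and reports explained variance floored at 0, with
`L` the source map length, so frequencies are in cycles per map length.
Orientation sampling is 36 steps of 5° over [−90°, 90°).

Indices: preferred frequency is the value-weighted mean of the tuning curve
`v(f) = max over orientations`; tuning width the area under the
peak-normalized `v(f)`; orientation selectivity `|F(1)|/F(0)` of the
orientation tuning curve (180° period), maximized over frequencies above
the cutoff (default 3 cycles, mirroring the dashed-line convention);
preferred orientation per frequency is the argmax (not a circular mean).
Orientation vectors use **raw** angles: doubling (the usual orientation
statistic) would map orthogonal orientations to antiparallel vectors with
zero cross product, defeating an index designed to be large exactly for
orthogonal gradient pairs. The orthogonality index is the maximum
cross-product magnitude over per-frequency vector pairs, invariant to
θ → θ+180° flips.

Empirically, planted orthogonal-gradient maps beat isotropic filtered-noise
maps on orientation selectivity and orthogonality (the discriminability the
acceptance suite checks); the frequency tuning *width* runs the other way —
noise has a broad, flat spectrum — so width discriminates multi-scale maps
from single-scale model maps (e.g. the SOM), not from noise.

## Models

Constraint functions and their scales are taken as given (`f(0) = 1` in all
cases; the Gaussian at σ = 1.25 mm is 9.7% ≈ 10% of peak at 2.7 mm, the
cortical point-spread anchor). The spatial loss averages
`(C_ij − f(d_ij))²` over unordered pairs, excluding pairs with undefined
profile correlation and reporting the excluded count.

The SOM places one unit per valid mask cell (positions in mm), initializes
weights as random unit vectors, and per step draws an input uniformly with
replacement, finds the winner by Euclidean weight distance, updates every
unit with rate `ηᵗ f(d_uv)` where `ηᵗ = T/(T+2t)`, and renormalizes weight
rows. Desk-scale default `T = 1e5` (the full `1e7` is a parameter; at
tested sizes the topographic ordering — contiguous winner domains for
antipodal input clusters — is established well before 1e5 steps).

The finite-difference ascender estimates the gradient as
`Σ_k (W(x+p_k) − W(x−p_k)) p_k/‖p_k‖` (no extra K or σ² scaling — the
literal form; any constant folds into the step size) and applies an
Adam-style step (lr 0.05, decays 0.9/0.999, K = 20, σ = 0.1 — package
defaults, recorded here because no canonical values exist). Paired
differences cancel even-order terms exactly, and the estimate is an
unbiased (up to scale) direction estimator on smooth objectives; it is
*not* deterministically proportional to the gradient for a finite
perturbation set.

## Surface geodesics

Edges require 3-D distance < 1 mm **and** flat-map distance < 1.5 mm, both
strict, weight = 3-D distance. Component merging is a single pass: for each
unordered component pair the minimal 3-D vertex distance is found; pairs in
the smallest 1% of those distances are joined at their closest vertex pair
(ties toward the lowest vertex-id pair) if that pair is under 1.5 mm on the
flat map. The percentile is over unordered component pairs. Geodesics are
Dijkstra shortest paths; distortion profiles compare geodesic to flat
distance for square pairs along caller-chosen orientations, representing
each 2-mm square by the vertex nearest (3-D) to the square's mean 3-D
coordinate, constrained to the largest component (nearest-member fallback).

## What the synthetic data do and do not show

The generators reproduce the *structural* properties each stage relies on:
non-Gaussian independent sources, periodic block responses with a phase
lag, white sensor noise, smooth oriented gradients, spatially correlated
map noise, mesh geometry. Passing tests therefore establish that the
implementations recover planted parameters under those assumptions at desk
scale (tens of voxels, ~10³ cells, 100-seed replications). They do not
establish robustness to real-data violations — HRF shape variation beyond a
delay, physiological noise with temporal autocorrelation, vascular
artifacts, non-Gaussian map noise, registration error — and no claim about
empirical effect sizes in real brains follows from them. Headline empirical
numbers from scanner data (noise-ceiling fractions, observed
dimensionalities, species differences) require the restricted data and are
deliberately out of scope; the one printed quantity that is purely
computational — the 14.9 chance-duplicate count — is reproduced exactly by
simulation.

## Problem sizes

Defaults in tests and examples are desk scale, chosen to exercise every
code path with comfortable statistical margins: 60-voxel scan sets with 25
axes and 2–4 scans; 150–400-cell maps; 100-seed replications for recovery
rates; 100 half-split iterations; SOM runs of 2·10⁴–5·10⁴ steps. Full-scale
values (500 GMM restarts, 500 half-splits, T = 10⁷ SOM steps, 10⁴
duplicate-chance rounds — the last is the default) are reachable through
the corresponding parameters.
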