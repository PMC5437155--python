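# Methods

## Data model

Each simulated subject m observes a time-by-voxel matrix

    D_m = A_m S_m + noise,     A_m: T x C time courses, S_m: C x V spatial maps,

with V = 148·148 pixels in the standard presets.  The C sources are
2-D isotropic Gaussian blobs derived from common templates; subject
variability enters through per-subject, per-source random translation
(N(0, 5 px) per axis), rotation (N(0, 3°)) and magnification
(N(3, 0.03)), applied about the blob centroid with bilinear
interpolation and clipping at the grid edge.  Subject-unique sources
are blobs placed independently per subject, uniformly over the grid
interior, at the same effective size as the magnified common sources.
Time courses are white Gaussian noise convolved with a canonical
double-gamma haemodynamic kernel sampled at TR = 2 s, standardized;
smoothing gives them the positive lag-1 autocorrelation of slow
haemodynamic fluctuations while leaving distinct columns uncorrelated
in expectation.

Noise is Rician: `sqrt((signal + baseline + n1)² + n2²)` with
independent Gaussians n1, n2 of SD σ.  The baseline (default 800×
the map peak) keeps the magnitude operation from rectifying signal;
temporal mean removal at analysis time cancels it.  σ is calibrated
from the target CNR as (mean temporal SD of the noise-free signal
over in-source voxels)/CNR, where *in-source* means the half-maximum
footprint of the sources — the same contour conventionally used to
display a source's extent.  A more inclusive footprint (e.g. every
voxel with any source loading) would average in near-zero taper
voxels and make data at a nominal CNR substantially cleaner; the
half-max convention places the CNR = 0.5…2 range in a regime where
estimation accuracy visibly degrades (mean spatial accuracy roughly
0.73 at CNR 0.5 rising to 0.97 at CNR 2), which is what a
quality-sweep experiment is designed to probe.

### What the simulator does and does not emulate

It reproduces linear mixing, spatially compact sources with
controlled inter-subject variability, super-Gaussian (sparse) spatial
distributions, haemodynamic-like temporal smoothness, and
Rician-distributed magnitude noise.  It does not model spatially
correlated noise, motion or scanner drifts, event/block task designs,
non-blob source shapes, or hemodynamic variability across regions.
Passing tests therefore show correctness of the algorithms and the
claimed comparative behaviour *under these conditions*; they do not
by themselves establish how the two methods rank on real data, where
source overlap, artifacts and model mismatch are richer.

## GIG-ICA

Stage 1 is temporal-concatenation group ICA: subject-level PCA to G1
(voxelwise temporal means removed; top eigendirections of the T×T
temporal covariance, whitened), concatenation, group PCA to G2, and
full-batch natural-gradient Infomax with a logistic nonlinearity.
The Infomax learning rate defaults to 0.1/ln(k) — the classical
per-block rate 0.015/ln(k) rescaled for full-batch updates — with
annealing (×0.9) and restart from the last stable iterate on a
blow-up; convergence is a relative weight-change below 1e-6.  Group
maps are sign-aligned to positive skewness and z-scored.

Stage 2 estimates each subject's component for each group IC r by
projected gradient ascent of `F(w) = λ·J(y) + (1−λ)·corr(y, r)` on
the unit sphere of the subject's spatially re-whitened G2-dimensional
space (rows exactly zero-mean, identity covariance, so `y = wᵀX` is
exactly standardized and `corr(y, r)` is linear in w).  The ascent
uses step halving on objective decrease (the recorded objective trace
is non-decreasing by construction), tolerance 1e-7, at most 1000
iterations per component.  λ defaults to 0.5; at λ→0 the estimate
reduces to the normalized projection of the reference onto the
subject's whitened space (PCA-style back-reconstruction), at λ→1 to
reference-initialized one-unit ICA.

Deflation: each component's starting vector is Gram–Schmidt
orthogonalized against previously accepted demixing vectors, which
places successive components in distinct basins, but the ascent
itself is unconstrained (`deflation="init"`).  Fully projected
deflation (`"hard"`) is available but forces exactly uncorrelated
maps, which cannot represent genuinely overlapping sources and makes
each component's estimate depend on every preceding reference —
incompatible with estimating a single network from a single external
spatial prior, a use the module supports by accepting any z-scored
map set as guidance.  On the standard 8-source design the soft scheme
keeps pairwise map correlations below 0.08.

Components whose final reference correlation falls below 0.2 are
returned but flagged.  Time courses are the least-squares solution of
`data ≈ tcs · maps` (right pseudo-inverse of the maps applied to the
temporally centered data).

## IVA-GL

Subject data are PCA-reduced and spatially re-whitened to I1
dimensions.  IVA-G minimizes `Σ_c ½ log det Σ_c − Σ_m log|det W_m|`,
where Σ_c is the M×M cross-subject covariance of component c; the
cost depends on the data only through the pairwise cross-covariance
blocks, which are precomputed once, so iterations are cheap.
Gradient descent starts from identity unmixing (the data are
whitened) with initial step 0.1/I1, halving on cost increase;
singular SCV covariances receive a small logged ridge.  IVA-L
refines with natural-gradient updates using the multivariate-Laplace
score `φ(y_m) = y_m/‖y_SCV‖₂`, warm-started from IVA-G, same
step-halving scheme.  Both cost traces are non-increasing.

Gradient steps cannot cross the discrete barrier between solutions
that differ by permuting one subject's component rows, yet such
permutations change how components group into SCVs and hence the
cost.  Two cost-guarded discrete moves are therefore interleaved with
the gradient phases: greedy within-subject row-swap polishing, and a
global realignment proposal that permutes every subject's rows to
match running cross-subject centroid maps.  Either move is accepted
only when it lowers the same IVA cost, preserving monotonicity.
Without them, a fraction of subjects can converge with the
subject-unique source parked at the wrong component index even though
the aligned solution has strictly lower cost.  IVA-G runs to
convergence (default iteration cap 16384 inside the pipeline; its
iterations touch only small matrices) because its solution seeds
IVA-L; a single seeded run is performed, with no multi-run selection.

Per-subject maps are sign-aligned to positive skewness and z-scored;
time courses are recovered through the PCA dewhitening and the
unmixing inverse, then standardized.  Because the TCs live in the
subject PCA subspace they are implicitly denoised, which is why the
temporal accuracy comparison can favour IVA-GL at low CNR even where
its spatial maps are less accurate.

## Evaluation

Estimated group-level maps (GIG-ICA: the group ICs; IVA-GL: the
voxelwise mean of subjects' z-scored maps per component index) are
matched to templates — the mean ground-truth map per source across
the subjects carrying it — by a greedy rule: repeatedly take the
globally largest remaining absolute correlation and delete its row
and column, ties broken lexicographically.  Greedy is not the optimal
assignment (a documented property: on [[0.9, 0.8], [0.85, 0.1]] it
pairs the diagonal for a total of 1.0 where the optimal total is
1.65); the Hungarian alternative is deliberately not the default.
The pairing propagates to subject maps and TCs; accuracy is the
absolute Pearson correlation with the matched truth.  Experiments
with subject-unique sources match against common-source templates
only, and the single leftover estimated component is scored against
each subject's unique source.  Methods are compared with two-tailed
paired t-tests across subjects (per-subject means, or per-component
vectors for the unique-source design), Bonferroni-corrected within
each experiment's family of computed tests.

## Reliability and network analysis

ICC uses the one-way ANOVA model with subjects as groups and k = 2
observations: σp² = max(0, (MSB−MSW)/2), σe² = MSW,
ICC = σp²/(σp²+σe²) ∈ [0, 1] (negative variance components clamped;
exactly constant columns defined as 0).  The estimator carries a
small O(1/n) ratio bias (about −0.015 at n = 25) and the clamp
inflates near-zero ICC by up to +0.05; recovery tests therefore
assert |bias| ≤ 0.05 on a (σp, σe) grid rather than literal
unbiasedness.  Short-term reliability compares scan 2 with scan 3;
long-term compares scan 1 with the mean of scans 2 and 3.  Voxelwise
significance masks come from right-tailed one-sample t-tests with
Benjamini–Hochberg FDR at q = 0.01, and network summaries average ICC
inside the intersection of both methods' masks.

FNC is the Pearson correlation matrix of component time courses.
Community detection is Newman's leading-eigenvector bisection with
greedy single-node fine-tuning, generalized to signed weights with
the asymmetric null-model weighting Q* = Q⁺ − (s⁻/(s⁺+s⁻))·Q⁻, which
reduces to classical Q on all-positive matrices (two disjoint
unit triangles give Q = 0.5).  Q values from this normalization are
bounded by 1 and are not comparable to toolbox variants that can
exceed it.  Modularity reliability uses adjusted mutual information
(permutation model, max normalization, symmetrized averaging); the
default pairing averages over *all* cross-scan dataset pairs, with a
subject-matched option (under which duplicated scans give AMI exactly
1).  Graph metrics at sparsity 0.5 (absolute values, top half of
off-diagonal pairs kept, ties at the cutoff kept) follow the standard
weighted definitions: node strength, geometric-mean triangle
clustering on max-scaled weights, and global/local efficiency with
path lengths 1/weight (unreachable pairs contribute zero).

## Numerical choices and degenerate inputs

- All arithmetic in float64; whitening eigenvalues floored at 1e-12.
- Zero-variance inputs raise (negentropy, accuracy, FNC columns) or
  are defined explicitly (p = 1 voxels in t-maps, ICC 0 for constant
  columns, Q = 0 for the all-zero matrix).
- Rank checks precede inversions: PCA beyond the numerical rank and
  rank-deficient map regressions raise with the rank or the most
  collinear pair named.
- Every stochastic routine takes an explicit seed; experiment presets
  derive all per-subject streams from one root seed, so outputs
  (including CSV bytes) are reproducible from (preset, seed) alone.

## Problem sizes

Unit tests run reduced designs (grids 20–64 px, 3–4 sources).  The
acceptance suite and `scripts/acceptance.py` run the full study
conditions — 10 subjects, 148×148 grids, 8 sources, 150 time points,
the complete 16-level CNR sweep and the 5-level time-point sweep —
chosen to match the standard design exactly.

## Known limitations

- The exact scalarization of the original multi-objective
  subject-IC optimization is not published in full detail; the
  λ-weighted form here is a documented stand-in validated by its
  limiting behaviour and the comparative properties in the test
  suite.
- Both optimizers here are monotone (line-searched, with permutation
  polishing for IVA); they land closer to their optima than
  fixed-schedule single-run implementations, so between-method
  accuracy gaps on clean data are smaller than historically reported
  and the associated t-statistics correspondingly nearer zero, with
  directions preserved.
- Real-data mode consumes already-preprocessed NIfTI volumes;
  slice-timing, realignment, normalization and smoothing are out of
  scope, and meaningful-network selection is an explicit user
  keep-list, never automated.
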