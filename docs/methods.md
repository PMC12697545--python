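# Methods

`axistrace` discovers population-level 3D-genome features — chromatin
loops, TAD boundaries and A/B compartments — from chromatin tracing data
(multiplexed DNA FISH), treating the three spatial axes as separately
measured, differently noisy views of the same underlying chromatin path.

## Model

A centered chromatin trace of `p` consecutive genomic bins is modeled per
axis as signal plus noise,

    x = x̃ + ε_x,   x̃ ~ N_p(0, K),   ε_x ~ N_p(0, σ²_x I),

with the same signal covariance `K` for x, y and z (they are views of one
3D curve) but axis-specific noise variances σ²_x, σ²_y, σ²_z.  Optical
microscopes localize spots with different precision laterally and axially,
so these can differ several-fold; methods built on the 3D Euclidean
distance implicitly weight all axes equally and inherit the worst axis's
noise.

All feature calling operates on per-axis pairwise differences
`x_ij − x_ik` across traces `i`: their variance is the axis component of
the squared 3D distance between bins `j` and `k`, so proximity structure
(loops, domains, compartments) is visible in each axis separately and can
be recombined with weights that favor the accurate axes.

## Axis weights

Assuming `K` is effectively low rank (most bins carry little independent
signal variance — the spiked-covariance regime), the per-axis noise
variance is estimated as the **median of the diagonal of the sample
covariance matrix**: the median over bins of the per-bin coordinate
variance across traces (pairwise-complete, denominator m−1).  Weights are
normalized inverse variances, `w_a ∝ 1/σ̂²_a`, summing to 1.

The estimator is consistent when the signal occupies a minority of bins.
On strongly polymer-correlated data every bin carries positional variance,
and the median diagonal then estimates noise **plus** a signal floor that
is common to all axes; the weight *ordering* is preserved but the weights
shrink toward uniform.  This is acceptable for combination purposes and is
the behavior on realistic backbones.

## Variance fields (filtering and normalization)

Per axis, the `n × p × p` difference tensor is reduced to `p × p`
sufficient statistics in four steps:

1. **Robust raw variance** per entry: `c · median_i[(d_i − median_i d_i)²]`
   over complete pairs, with the Gaussian consistency constant
   `c = 1/Φ⁻¹(0.75)² ≈ 2.1981`, so the robust value is on the ordinary
   variance scale.  Entries with fewer than 3 complete pairs are NaN; the
   diagonal is excluded.
2. **Expected-variance curve**: a lowess fit (fraction 0.3, 3 robustifying
   iterations, each finite matrix entry one point) of raw variance against
   1D genomic separation `s = |j−k|·resolution`, linearly extrapolated at
   the ends and floored at 1 nm².  This captures polymer distance decay.
3. **Outlier filter**: a difference survives iff `|d| ≤ 4·√E(s)`.  The
   Z-score is taken about 0, not the entry median, because pairwise
   differences are symmetric about 0 under random chromosome orientation;
   this also lets the filter operate on `|d|` alone.  Under Gaussian data
   the filter removes `2Φ(−4) ≈ 6.3·10⁻⁵` of differences.
4. **Filtered, normalized variance**: the ordinary (mean-based) sample
   variance of surviving differences per entry (denominator C−1, C the
   surviving count), refit with a second per-axis lowess curve and divided
   by it.  The result `V_a` has unit scale: entries fluctuate around 1
   under no structure.

**Sufficient-statistics contract.**  Every downstream test uses only
`(V_a, C_a)` with count weights: a pooled variance over an entry set is
`Σ (C−1)·V / Σ (C−1)` with `Σ (C−1)` degrees of freedom, identical (to
machine precision; verified to 1e−9 in tests) to pooling the raw filtered
differences normalized by their expected variances.  Peak memory is
O(p²) per axis plus one `n × p` buffer; the full difference tensor is
never materialized.

## Loop calling

For a tested pair `(j, k)` (anchor separation ≥ 100 Kb by default) the
local background is the Chebyshev ring of pairs whose anchors are
displaced 25–50 Kb (1–2 bins at 25 Kb) from `(j, k)`, excluding the pair
itself and near-diagonal entries.  Per axis, a lower-tail F test compares
`V_a(j,k)` (df C−1) with the pooled ring variance; pairs with fewer than
3 valid ring entries or fewer than 3 surviving differences are untested.
Axis p-values are combined by the weighted aggregated Cauchy (ACAT)
statistic

    T = Σ_a w_a · tan((0.5 − p_a)π),    p = 0.5 − arctan(T)/π,

with NaN axes dropped and weights renormalized, and p-values clipped to
[1e−15, 1−1e−15] before the tangent.  BH FDR < 0.1 defines candidates;
candidates within 50 Kb (Chebyshev on anchors) form clusters; the
minimum-p member of each cluster is the summit (ties broken
lexicographically); summits are kept if p < 1e−5, and optionally filtered
by population contact frequency (fraction of co-observing traces with 3D
distance < 500 nm): ≥ 1/3 for cluster summits, ≥ 1/2 for singletons.
The frequency filter is off by default, mirroring its dataset-specific
use.

## TAD boundaries and hierarchy

Each bin `i` is scored within a 200-Kb window per side (8 bins at 25 Kb;
the "window surrounding each segment" reading is per-side, configurable).
Upstream bins U and downstream bins D exclude the tested bin; bins with
less than half a side available are excluded.  Per axis, the pooled
variance of U×D (inter-domain) entries is tested against the pooled
variance of within-U plus within-D (intra-domain) entries with an
upper-tail F test; combination and FDR as for loops.

With thousands of traces the exact p-values saturate at 0/1, so peak
finding uses an **F(1,1) approximation**: the same variance ratios
referred to an F distribution with both dfs equal to one, a heavy-tailed
reference that stays graded.  Local minima of this approximate profile
(interior, strict-neighbor, plateaus counted once at their leftmost bin)
whose exact-df FDR is below 0.1 are the boundaries.  Peak finding runs on
the approximate p-values rather than their BH adjustment: step-up
adjustment is a monotone transform with suffix-min flattening that ties
neighboring values into plateaus (for F(1,1) p-values, which never fall
far below ~0.2, the adjusted profile is in practice entirely flat), while
the unadjusted profile preserves the minima.  The adjusted values are
still reported.

Hierarchy: level-0 intervals tile the region between consecutive
boundaries; boundaries are then removed in increasing order of their
Cauchy statistic T, and each removal appends the interval between the
removed boundary's surviving neighbors (or region ends) with the level
incremented once per removal.  Every level-ℓ ≥ 1 interval is a union of
contiguous lower-level intervals.

## A/B compartments

Per axis, the normalized variance matrix (NaNs imputed by their
genomic-distance-stratum mean, the diagonal set to 0, which shifts the
spectrum but not the eigenvectors) is eigendecomposed; eigenpairs are
ordered by |eigenvalue| since the normalized matrix is not positive
semidefinite.  The **second** eigenvector is kept per axis (the first
tracks residual distance decay), sign-fixed, giving a `p × 3` embedding.
Rows are scaled by the axis weights and clustered with 2-means (10
restarts, fixed seed).  The cluster overlapping more TSSs is A; without
a TSS annotation the cluster with lower within-group weighted variance is
B (condensed heterochromatin), with the variance rule also breaking TSS
ties.  An optional centromere coordinate runs the pipeline per arm.

The weighting is what confers robustness to whole-chromosome confounders:
when the two arms separate rigidly in the noisy axes, the second
eigenvectors of those axes encode the arm split, but their weights are
small, so 2-means follows the accurate axis instead.

## Synthetic data

`simulate_planted` draws traces per axis from `N(0, K_axis)` built from
the cumulative random-walk kernel `K0(j,k) = scale²·min(j+1, k+1)`
(pairwise-difference variance grows linearly with separation, emulating
polymer distance decay), plus planted features:

* **Loops** — a symmetric contraction of the two anchor coordinates
  toward each other (`x_j' = (1−t)x_j + t x_k` and vice versa with
  `t = (1−√α)/2`), which multiplies the anchor-pair difference variance
  by exactly the proximity factor α and keeps K positive semidefinite by
  construction.  A direct covariance edit of the single entry cannot
  achieve a meaningful local shrink inside the PSD cone (the chain pins
  each anchor to its neighbors), so the contraction — which also slightly
  moves the anchors' other pairings, as a physical loop would — is the
  planting mechanism.
* **Boundaries** — cross-block covariance multiplied by the insulation
  factor (per crossed boundary), inflating cross-boundary difference
  variances.
* **Compartments** — a rank-1 label factor `K += τ²·ss'` with `s = ±1`
  block labels: cross-label difference variances gain a uniform `4τ²`
  (checkerboard), PSD by construction, optionally restricted to a subset
  of axes.
* **Arm confounder** — an independent per-trace rigid displacement of the
  second half of the region on chosen axes.

Per-axis Gaussian noise is added and spots are masked at the missing
rate (default 0.1).  `simulate_spiked` provides the sparse low-rank
design (rank-r signal confined to a few bins) in which the
median-diagonal noise estimator is consistent.  `resample_uniform_noise`
mirrors the experiment-based simulator: three x-axis profiles from three
distinct traces form one new trace, so all axes share one noise level;
`add_axis_noise` injects additional axis-specific Gaussian noise
(0–200 nm SDs are the plausible range given reported ~30–70 nm median
displacement errors plus drift/aberration corrections).

### Study conditions

The canonical scenarios (fixed defaults; also used by
`scripts/acceptance.py`):

| scenario | n | p | key settings |
|---|---|---|---|
| null / pure noise | 500 | 60 | no planted features; pure-noise variant sets scale ≈ 0 |
| loops | 250 | 60 | anchors (10,30), (20,45), (35,55), proximity 0.30/0.40/0.50 |
| TADs | 400 | 60 | boundaries {12, 24, 36, 48}, insulation 0.4 |
| compartments | 30 | 60 | blocks of 10, τ = 100 nm on z only; noise (250, 250, 50) nm; arm displacement 400 nm SD in x/y |

Resolution 25 Kb, backbone scale 150 nm/step (50 nm in the compartment
scenario's weaker-backbone, whole-chromosome-like regime), noise 100 nm
per axis unless stated.  Loop proximity factors are graded so that the
planted p-values stay distinguishable above the 1e−15 clip, making rank
stability across noise conditions measurable; the compartment scenario
reproduces the regime where lateral (x/y) uncertainty exceeds axial (z)
and the compartment signal lives in the accurate axis.

### What the simulations do and do not show

The generators produce Gaussian traces with covariance-level features.
They do not emulate looped/unlooped cell subpopulations, chromosome
territory shapes, locus-dependent detection efficiency, or segmentation
errors, so passing tests demonstrate the statistical machinery under the
stated model, not end-to-end performance on any specific experimental
dataset.

## Calibration and known limitations

* Under a structureless Gaussian null (exchangeable noise, no backbone),
  per-axis loop p-values are uniform to within a KS deviation of
  ~0.012–0.015 — a mild underdispersion caused by the positive correlation
  between a tested entry and ring entries sharing an anchor (they share a
  noise term).  Candidate counts at FDR 0.1 are ~0 for both loops and
  boundaries.
* Under strongly polymer-correlated backbones, entries pooled into
  backgrounds or inter/intra sets share genomic spans, so the nominal
  pooled degrees of freedom overstate the independent information: loop
  p-values become conservative, and the boundary test becomes **liberal**
  (spurious FDR < 0.1 bins on pure random-walk data).  The local-minimum
  rule and the final p-value/frequency filters are what keep calls
  specific in this regime; boundary FDRs should be read as ranking scores
  rather than frequentist error rates on highly correlated data.
* The F(1,1) approximation is used for peak *location* only; exact-df
  FDRs gate the final calls.
* The median-diagonal noise estimator absorbs a common signal floor on
  non-sparse data (see above); weights then understate the true
  noise-precision ratio but keep the correct ordering.
* Numerical conventions: p-value clip 1e−15 before the Cauchy transform;
  lowess floor 1 nm²; robust-variance consistency constant 2.1981;
  summit/cluster ties broken lexicographically on (j, k); eigenvector
  signs fixed by the first non-negligible component; K-means seed 0 with
  10 restarts.
* Degenerate inputs: bins with too few observations are NaN and excluded
  from medians/pools; untestable axes are dropped from the Cauchy
  combination with weight renormalization; all-NaN combinations are NaN;
  traces with no observed spots are dropped with a warning.
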