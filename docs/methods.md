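# Methods

This note documents the models and procedures implemented in `mccims`,
the assumptions behind them, the parameters that matter, and the design
choices made where the methodology left the design open.

## Data model

An MCC/IMS measurement is an `|R| × |T|` matrix `S` of signal
intensities over two time axes: `T`, the inverse reduced mobility
(1/K₀, Vs/cm²), a drift-time axis normalized to be independent of tube
length, field strength and gas flow; and `R`, the retention time (s) of
the multi-capillary column. A row of `S` is a *spectrum*, a column a
*contour line*. A peak is the tuple `(i, r, t, s)`: measurement id,
retention time, inverse reduced mobility, and intensity. Every spectrum
contains the reactant ion peak (RIP) near 0.46 Vs/cm², a persistent
band present at all retention times.

## Homogenization

A measurement set is comparable only if the device settings agree:
drift and sample gas flow 100 ± 5 mL/min, carrier gas flow
150 ± 5 mL/min, column temperature 40 ± 2 °C (boundaries inclusive),
and one drift gas and one polarity across the set. "One value for the
set" is operationalized as the majority value; minority measurements
are rejected, and an exact tie rejects nobody but logs a warning (no
principled winner exists). All measurements are then truncated to a
common retention window: spectra before 5 s are instrument artefacts
and are dropped (r = 5 s itself is kept), and the *cut-off time* — the
smallest maximum retention time over the set — trims the long end.
Truncation is idempotent.

## Preprocessing

Four stages in fixed order, all dimension-preserving:

1. **RIP compensation** — subtract the median of each contour line from
   that column. Because the RIP is roughly constant over retention
   time, the column median estimates its profile and removes it while
   leaving localized peaks (which occupy few rows of any column)
   almost untouched. Negative residuals are kept; clipping would bias
   later stages, and detectors threshold anyway.
2. **DFT low-pass** — 2-D FFT; coefficients whose frequency index on
   either axis exceeds `dft_keep_fraction` (default 0.25) of the
   Nyquist band are zeroed; inverse transform, real part. DC is always
   kept, so constant grids pass unchanged.
3. **Gaussian blur** — separable convolution, `σ = 2` cells per axis by
   default, kernel truncated at 4σ, edge replication at the boundary
   (avoids the dark frame a zero-padded boundary would create).
4. **Savitzky–Golay** — each spectrum is smoothed along the drift axis
   by a moving least-squares polynomial fit, window 9 points, degree 2.
   Terminal windows are filled by evaluating the polynomial fitted to
   the edge window, so degree-≤2 signals are reproduced exactly
   everywhere.

The low-pass fraction, blur σ and polynomial degree are gentle-smoothing
defaults chosen for desk-scale grids; all are configurable.

## Peak detectors

**Local maxima search (LMS).** A cell is a local maximum if it strictly
exceeds all 8 neighbors (plateaus are therefore not maxima). It is
reported only if its neighborhood is *significant*: the cell and its 8
neighbors all exceed the intensity threshold `I = 10`, and at least
`A = 2` additional adjacent cells do too. "Additional adjacent" is read
as the 16-cell perimeter of the 5×5 window — the cells adjacent to the
3×3 block; perimeter cells outside the grid count as failing. "At
least A" (rather than exactly A) is used. All threshold comparisons are
strict.

**Watershed.** A water level is lowered over the intensity landscape.
Continuous data makes discrete levels degenerate, so the implementation
is the deterministic limit: cells are processed in strictly descending
intensity (ties broken by row-major position), stopping below
`min_level = 10` (matching the LMS threshold, for comparability). A
cell touching a labeled cell (8-connectivity) inherits the label of its
highest-intensity labeled neighbor (ties → lowest label id); an
unconnected cell founds a new label, and each founding cell is reported
as a peak.

**Region merging.** Cells are split into peak/non-peak classes by a
deterministic 1-D 2-means over all intensities (centers initialized at
the min and max, Lloyd iterations to a fixed point; a cell belongs to
the higher-center class if it lies above the midpoint of the two
centers). Peak cells are linked into 8-connected regions; regions
smaller than 5 cells are discarded as noise (the method otherwise
reports every speckle). Each region is summarized by its *centroid
point*: the member cell with the smallest mean Euclidean distance — in
grid-index space, since the axes' physical units are incommensurate —
to the other members, ties broken by higher intensity then row-major
order.

**Peak model estimation (PME).** Each peak is modeled as a volume-
weighted product of two shifted inverse Gaussian (IG) densities

    f(x; μ, λ, o) = sqrt(λ / 2π(x−o)³) · exp(−λ((x−o)−μ)² / 2μ²(x−o)),  x > o,

one along each axis — right-skewed, matching the tailing of real
peaks; its mode is `μ·(sqrt(1 + 9μ²/4λ²) − 3μ/2λ) + o`, a continuous
position that need not lie on the grid. Normalized cell intensities
(clipped at zero inside this module only — the mixture needs
non-negative mass) are treated as a weighted sample over `(t, r)` and
fitted by EM with one component per seed plus a uniform noise component
over the grid rectangle. Seeds are cells where the discrete first
derivative changes sign from + to − along both the spectrum and the
chromatogram and intensity is ≥ 10; any external peak list can be
substituted.

Offsets are held fixed during EM, which gives closed-form M-steps: with
responsibilities `γ`, the updates are `μ = Σγw(x−o)/Σγw` and
`1/λ = Σγw(1/(x−o))/Σγw − 1/μ`, the weighted IG maximum-likelihood
estimates. Each offset is pinned `offset_halfwidths = 5` left
half-widths (at half maximum, measured from the seed along its axis)
below the seed. A *width-scaled* margin is essential: a fixed margin in
cells either truncates the left flank of wide peaks (support excludes
real mass, which then leaks into the noise component and biases the
mode) or collapses for narrow ones; scaling by the observed half-width
keeps the whole flank inside the support at any grid resolution, and
the IG's sharply vanishing left tail makes a generous margin harmless.
Iteration stops when the relative log-likelihood change falls below
1e−6 (or at 200 iterations); the log-likelihood is non-decreasing and
mixture weights sum to one after every M-step (both are asserted).
Components with weight < 1e−4 are dropped; a reported peak carries the
component's marginal modes and intensity `s = weight × total grid
mass`, i.e. the model's estimate of the peak volume. In recovery
simulations this is within a few percent of the injected mass.

## Merging, clustering, feature matrix

Two peaks P, Q with `s(P) ≥ s(Q)` describe the same compound if
`|t(P) − t(Q)| < 0.003` Vs/cm² and `|r(P) − r(Q)| < 3.0 + 0.1·r(P)` s —
the retention tolerance widens with retention time because peaks
broaden as they elute later. Within a measurement, peaks are swept in
descending intensity (ties by `(r, t)`), and a peak is dropped iff it
is mergeable into an already-retained peak; the sweep is a single pass
over the pre-sorted list and is idempotent. The same sweep over the
pooled peaks of all measurements — ignoring measurement identity —
forms *peak clusters*: a peak joins the first retained founder it is
mergeable into (first-founder, not best-founder, mirroring the sorted
sweep), else founds a new cluster at its own position. If several peaks
of one measurement fall into a cluster, the maximum intensity is kept.
The feature matrix has one row per measurement and one column per
cluster (absent = 0), columns ordered by descending total intensity,
plus a class label K (control) or D (diseased) per measurement.
Manually curated peak lists, which arrive already clustered per
measurement, can bypass the within-measurement merge.

## Detector comparison

For peak lists V, W, peak P ∈ V *maps* to Q ∈ W if both are from the
same measurement and satisfy the position tolerances above, with the
retention tolerance computed from `r(P)` and no intensity ordering —
dropping the intensity clause is what makes the relation, and the
resulting count table `(V, W) ↦ #{P ∈ V : ∃Q ∈ W}`, asymmetric. Every
peak maps to itself, so the table's diagonal equals the list sizes.

## Classification benchmark

The feature matrix is evaluated with a linear SVM (cost 100, tolerance
0.01) and a random forest (500 trees, √p features per split, class-
probability scores), in balanced (stratified) 10-fold cross-validation
repeated with fresh fold assignments (100 repeats at full scale; the
bundled tests and the acceptance script use 20 and 10–20 respectively
to keep runtimes at desk scale). Per repeat, held-out scores are pooled
over folds into a single metric set — pooling is stabler than fold
averaging at n ≈ 69 — giving accuracy, AUC, sensitivity, specificity,
PPV and NPV at threshold 0.5 with D as the positive class; metrics with
zero denominators are reported as undefined rather than 0. AUC is the
Mann–Whitney rank statistic (ties count ½). SVM decision values are
mapped to [0, 1] by logistic calibration fitted on the training fold;
SVM features are z-scored with statistics from the training fold only
(raw intensities span orders of magnitude, which makes a cost-100
linear SVM ill-conditioned; the forest is scale-invariant and uses raw
features). A tuning grid varies the SVM cost over {0.1, 1, 100, 1000}
and tolerance over {0.01, 0.1, 1} with one balanced 10-fold CV per
combination, optionally on permuted class labels to expose overfitting:
separable data should lose its signal under permutation, and a method
whose permuted-label performance stays high is fitting noise.

## Synthetic cohort

Clinical breath data is confidential, so the benchmark ships a
simulator with known ground truth. A measurement is built additively
on a desk-scale grid (300 retention × 500 drift cells by default,
configurable up to instrument resolution of 12,500 points per
spectrum): a RIP band (Gaussian profile in t, height 400, σ 0.008
Vs/cm², constant over r — constant-over-r is exactly the structure the
median-per-contour-line filter removes); eight compound peaks, each a
volume-weighted product of two shifted IG densities with modes placed
via a helper that inverts the mode formula; a baseline of 2; and
i.i.d. Gaussian noise with σ = 1. Peak volumes (35–65 signal·cell
units) put post-preprocessing apex intensities near 100–190, an order
of magnitude above the detection thresholds — a regime where all four
detectors operate non-trivially but reliably. The cohort is 30 control
(K) and 39 diseased (D) measurements; three of the eight peaks carry a
multiplicative class effect on volume (×1.8, ×0.55, ×2.2) emulating
up- and down-regulated compounds.

Per-measurement positional jitter is a *clipped* Gaussian (±1.8 SD,
default SD 0.0005 Vs/cm² in t and 1.0 s in r): the bounded support
guarantees that all realizations of one designed peak stay within the
merge tolerances of each other, so the designed number of clusters is
exactly recoverable — an unbounded Gaussian would split clusters with
small but non-zero probability and make ground-truth assertions flaky.
Per-measurement seeds are derived deterministically from the master
seed.

The simulator deliberately omits several features of real data:
per-measurement multiplicative intensity noise, correlated (non-white)
baseline drift, retention-time warping between measurements beyond
rigid jitter, overlapping/shouldered peaks, and detector saturation.
Passing tests therefore demonstrate correctness of the algorithms under
the stated model, not field performance on clinical measurements.

## Numerical choices and degenerate inputs

- Intensity ties in the watershed and merge sweeps are broken by grid
  position / `(r, t)` so every run is deterministic.
- The 2-means binarization rejects constant grids (no two-class
  structure exists).
- EM raises on a non-finite log-likelihood, reporting the iteration;
  starved components (responsibility mass ~0) keep their parameters
  instead of dividing by zero; `1/λ` updates are floored at 1e−12.
- Measurement files store values at full float precision (`%.17g`), so
  write→read round trips are bit-exact; CSV readers use pandas'
  round-trip float parser for the same reason.
- Stratified folds, label permutations and forest seeds all derive from
  one master seed; an entire pipeline run is byte-reproducible.

## Known limitations

- The PME noise model is uniform; structured background (e.g. RIP
  residues) can inflate component tails.
- Region merging's 2-means on heavily skewed intensity distributions
  places the class boundary high, so weak peaks may be missed — a
  behavior characteristic of this detector family rather than a bug.
- The overlap comparison counts position-compatible peaks only; it says
  nothing about intensity agreement.
- With strong class effects and no intensity noise, the default cohort
  is close to linearly separable; classification AUCs near 1 are
  expected by design and should not be read as estimates of clinical
  performance.
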