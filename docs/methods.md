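# Methods

## Scene model

A scene is a 2D scale model of the microdevice chamber: a
`width_mm x height_mm` rectangle sampled at `pixel_size_um`, lumen at
`x = 0`. Defaults (12 mm x 5 mm at 62.5 µm → a 192 x 80 px frame) keep
whole-chamber simulations cheap; the frame is a scale model, so cells
are a few pixels across and only relative positions and effect sizes
are meaningful, not absolute optical resolution. The proximal band is
the first 25% of the chamber length; the distal band starts at
`distal_offset_mm` (default 10 mm, the conventional definition of the
distal analysis region).

Cells are discs (radius per density label) with a concentric dim
nucleus at 35% of cytoplasm brightness — nuclei appear dark in
cytoplasmic autofluorescence, which is what the nuclei detector
exploits. Centers are drawn by rejection sampling so nuclei never
overlap; cell bodies may overlap, as in dense tissue, and overlapping
pixels belong to the nearest cell (radius-normalized), except that any
pixel inside a nucleus is always rendered at nucleus brightness.

Density labels map to `(cell count, cell radius, nucleus radius)` =
low (120, 4.5, 2.2), high (280, 3.2, 1.6), extreme (380, 3.0, 1.5) in
the default frame. The experimental seeding densities (3, 15, 30
million cells/mL) are kept as labels only: a 2D frame saturates well
before a linear 1:5:10 count scaling, so rendered counts grow
sublinearly and cells shrink with crowding. Downstream checks depend on
programmed effects and gradients, not on absolute density.

### Viability gradient

Each cell's alive flag is Bernoulli with probability given by a
logistic profile along the chamber axis,
`p(x) = p_dist + (p_prox − p_dist) / (1 + exp((x − m)/s))`, with
plateaus `p_prox`, `p_dist` per condition and density, midpoint
`m = 0.55·W` and steepness `s = 0.08·W` by default. The necrotic-core
scene overrides the midpoint: a programmed core fraction `f` sets
`m = (1 − f)·W` with a sharp slope, so dead cells dominate the distal
`f` of the chamber. The plateaus are fixed per condition and density
(e.g. low-density glycolysis inhibition: 75% everywhere; high-density
control: 87% proximal / 50% distal) — these programmed levels define
the study conditions the recovery benchmarks measure against.

### Decay model and condition effects

Per-cell true decay parameters start from representative
literature-range values — NAD(P)H α₁ = 0.70, τ₁ = 400 ps, τ₂ = 2500 ps;
FAD α₁ = 0.60, τ₁ = 300 ps, τ₂ = 2300 ps — with 3% per-cell lifetime
jitter and a mean-one lognormal brightness factor (CV 10%) common to
both channels (so it cancels in the redox ratio). The baseline redox
ratio is 1.5 (FAD at 1/1.5 of the NAD(P)H photon budget). Only recovery
of whatever is programmed is ever asserted, never these baselines.

Treatment effects are multiplicative and position-interpolated with the
same logistic form: the redox multiplier scales the NAD(P)H photon
budget (e.g. 0.60 for high-density glycolysis inhibition — the
programmed 40% decrease), and a lifetime multiplier scales NAD(P)H τ₁
and τ₂. Effects apply to **all** cells, not only the ones flagged
alive: the FLIM channels represent the imaging time point, which in the
experiment precedes necrosis, while the alive flags represent the later
staining time point. This separation also keeps the normalized redox
effect well defined when treated and control scenes have different dead
fractions.

### Rendering

Expected counts per pixel and time bin are
`budget · (IRF ⊛ decay)/Σ + background_rate`, where the convolved shape
is normalized to unit sum inside the window so the photon budget is
conserved exactly (noiseless rendering reproduces the per-pixel budget
to rounding). Observed counts are Poisson. The acquisition grid is
256 bins over 12.5 ns (one 80 MHz laser period); the default budget is
150 photons per bright pixel with 0.005 dark counts per bin.
Incomplete-decay wrap-around is ignored (linear, not periodic,
convolution) — justified because τ₂ ≲ 3 ns ≪ 12.5 ns; a documented
limitation. Viability images render each cell as a blurred disc at 55%
of the cell radius in its channel (green live, red dead) over a flat
background with Gaussian read noise.

## Decay fitting

"Deconvolution with the IRF" is implemented as iterative reconvolution:
the model is convolved forward and compared with the data, the standard
numerically stable reading. The exponential is represented by its
**bin-integrated kernel** `K[m] = (τ/Δt)(e^{−a/τ} − e^{−b/τ})` over each
bin's lag interval, which handles the causal step at lag zero exactly;
a point-sampled kernel is biased by O(Δt/τ) there (≈6% at τ = 400 ps).
The convolution with the sampled IRF reduces to an O(n) cumulative sum,
and the result matches a 40x-oversampled brute-force convolution to
<0.5% of peak per bin (a frozen test).

The fit minimizes weighted least squares with Neyman weights
`1/max(counts, 1)` — a Poisson-motivated approximation that keeps the
least-squares contract testable; full Poisson maximum likelihood would
be the natural alternative and is deliberately not the default. The
nonlinear search runs over the lifetimes only (`scipy`'s trust-region
reflective within bounds τ₁ ∈ [50, 1500] ps, τ₂ ∈ [800, 6000] ps); for
fixed lifetimes the component photon counts and background are linear
and are profiled out by a non-negative linear solve (normal equations
with an `nnls` fallback). This variable-projection form minimizes the
same objective as a joint 5-parameter search at a fraction of the cost,
which is what makes whole-image fitting practical. Fitted photon counts
per component are converted to t = 0 amplitude fractions
(`αᵢ ∝ aᵢ/Sᵢ`, with `Sᵢ` the component's window sum) — photon fractions
and amplitude fractions differ by a factor ≈ τᵢ, an easy mistake the
tests pin down. Lifetime ordering (τ₁ ≤ τ₂) is enforced by swap, `τₘ`
is the amplitude-weighted mean, and χ²_reduced is reported.

Image fitting sums 3x3 neighborhoods (binning radius 1) before fitting
so pixels reach the 500-photon threshold, mirroring common TCSPC
software practice; the intensity map stays unbinned. Pixels below
threshold are NaN/masked, never exceptions. Known bias: at ~1000
photons per fit the bi-exponential τₘ is 5–10% low (weighted-LS
small-count bias); it cancels in control-normalized comparisons and
disappears at the 10⁴–10⁵ photon budgets where recovery is asserted.

## Redox metrics

Per-pixel redox ratio is NAD(P)H/FAD of the **total-photon** intensity
images (not fitted amplitudes — the simplest reading of intensity);
zero-FAD pixels are masked. Per-cell values average the per-pixel ratio
over the cytoplasm (ratio-then-average, matching the per-pixel
definition followed by cytoplasm averaging); a sum-then-ratio mode
exists behind a flag. Normalization divides each cell by the mean of
control cells at the same position label and therefore leaves control
groups at mean exactly 1. The small residual compression from dark
counts entering both intensities (&lt;1 point at default budgets) is the
main reason recovered decreases sit ≈39% rather than exactly 40%.

## Segmentation

Nuclei: smooth (σ = 0.5 px), split background from cells with a global
Otsu threshold, fill holes (nuclei are dimmer than the background
split), erode the foreground by 2 px to drop cell-rim pixels, then
split nucleus from cytoplasm with a second Otsu computed **within** the
foreground only — a background-dominated histogram would misplace a
single global split. Candidate components are area-filtered
(4–400 px) and touching candidates split by a distance-transform
watershed. Detection counts are scale-invariant (both thresholds scale
with intensity).

Cells: watershed over the geodesic distance from the nearest nucleus,
masked to the hole-filled Otsu foreground — the distance-regularized
"propagate" recipe. Flooding inverted intensity directly proved
inequitable on dense plateaus (single labels swallowing clusters); an
optional weight blends inverted intensity into the cost for boundary
refinement. Cytoplasm is the label-preserving set difference cell minus
nucleus; entirely-nuclear cells are dropped from the table with a
warning. Aggregation takes NaN-aware cytoplasm means per cell, assigns
position labels from centroids, and flags QC when fewer than 100 cells
are analyzed.

## Viability quantification

Objects are segmented on the green+red sum (one object per stained
cell regardless of class), split by a distance watershed, and
classified by the larger background-subtracted channel mean; exact ties
count as dead (conservative). Percentages are object-count based,
matching per-cell bar-graph readouts (an area-weighted mode exists).
The necrotic-core extent divides the axis into 20 bins, calls a bin
necrotic when dead objects strictly outnumber live ones, and measures
the longest necrotic run anchored at the distal wall — anchored there
because that is where the core forms.

## Statistics

Per metric and position stratum: Kolmogorov–Smirnov normality per group
(against a normal fitted to the sample — reported, never gating, and
without a Lilliefors correction), Kruskal–Wallis across conditions,
then two-sided Mann–Whitney U of each treatment against control, with
stars at p < 0.05 and p < 0.001. No multiple-testing correction by
default (a Bonferroni option exists). Groups need ≥3 observations;
undersized strata are skipped with a warning. The normality check and
the nonparametric cascade are both reported without resolving the
tension between them — that mirrors standard practice in this assay
class.

## Recovery benchmarks and problem sizes

`scripts/acceptance.py` and the acceptance tests regenerate everything
from seeds: the 2.1 ns mono-exponential standard (7 replicates at 10⁵
photons), the 244 ps IRF width, the end-to-end 40% redox-decrease
recovery on paired high-density scenes (the heaviest step: ~35 000
per-pixel fits across two channels and two scenes), viability
percentages averaged over 5–8 replicate scenes (single scenes carry
4–8 points of binomial noise at ~100–170 objects, so replicate
averaging — like repeated experiments — measures the programmed level
rather than one draw), the necrotic-core extent over 3 replicates, and
the ≥100-cell segmentation QC. The test suite runs the same checks on
moderately sized frames (e.g. a 160 x 67 px high-density pair) to stay
fast; sizes are package choices made once, recorded here.

## Limitations

- No optics: no PSF, no detector afterpulsing, no photobleaching,
  discs instead of real cell morphology, no nutrient-diffusion PDE —
  the gradient is imposed, not mechanistic.
- Passing recovery on synthetic scenes shows the analysis inverts its
  own forward model at realistic noise levels; it cannot certify
  performance on real microscopy with autofluorescence backgrounds,
  optical sectioning artifacts, or vendor-specific IRFs.
- Equivalence to commercial TCSPC fitting software is not asserted;
  only recovery of programmed truth is.
- The daily-standard and IRF checks are deterministic given the seed;
  optimizer outputs are reproducible to floating-point determinism on
  one platform.
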