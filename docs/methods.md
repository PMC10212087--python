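# Methods

## Scope and design

The package reimplements two lab analyses as one pipeline with a
synthetic front end: (a) cantilever-based spheroid compression →
Young's modulus, and (b) TEM cross-section morphometry → cell/nucleus
areas and intercellular-space density. Raw experimental images are not
publicly deposited, so the synthetic generators are first-class, tested
code: they encode the study conditions as presets and return exact
ground truth, which is what the test suite and the acceptance script
measure against.

## Contact model and modulus fit

A spheroid is modeled as a homogeneous, isotropic elastic sphere of
radius R compressed between two rigid plates (the cantilever tips). Each
plate contact is a small-strain Hertz sphere-on-flat contact carrying
half the total compression δ:

    F(δ) = (4/3) · E/(1−ν²) · √R · (δ/2)^{3/2}

Design notes:

* **Closed form instead of finite elements.** The original analysis used
  an FE model that is not specified beyond "a sphere"; the two-plate
  Hertz closed form is the standard small-strain description of that
  geometry, is exactly invertible, and makes modulus recovery testable.
  Absolute agreement with an unspecified FE model is not claimed; the
  acceptance checks are model-consistent parameter recovery plus the
  printed force-ratio, which under linearity in E is exactly E₂₀/E₅.
* **ν = 0.5 default** (incompressible soft tissue), configurable. ν is
  not reported for these spheroids; it only rescales E by (1−ν²) and so
  cancels out of the recovery tests (generator and fit share it).
* **Rigid plates.** Tip compliance beyond the beam spring constant and
  tip curvature are ignored; the tips are far stiffer and flatter than
  the spheroid at the contact scale.
* **Fit:** F is linear in E, so E = Σ(g·F)/Σ(g²) over post-contact
  points with g(δ) the geometry factor — exact zero-intercept least
  squares, no iterative optimizer, no tuning. A brute-force grid scan
  (`modulus_oracle`) provides the independent verification path.
* **Large strains.** Late compression steps reach δ/2R ≈ 0.2–0.25, past
  the strict Hertz validity range. Both generator and fit use the same
  law, so recovery is unaffected; against real data the fitted E is an
  effective small-strain modulus, as in the original analysis.

## Cantilever and actuation

Spring constant k = 3·E_c·I/L³ with I = w·t³/12 (Euler–Bernoulli tip
load). With the printed geometry (L = 1.6 mm, w = 100 μm, t = 15 μm) and
an SU-8-like E_c = 4 GPa this gives k ≈ 0.0824 N/m, which maps the
0.5–8 μN contact forces of these spheroids onto optically resolvable
5–100 μm deflections. The physical instrument's calibrated constant is not
public; k is configurable (explicit value overrides geometry).

Actuation: 1.1 V/step from 0 to 40 V → 36 steps; gain 4.9/1.1 μm/V so
each tip advances 4.9 μm/step. The published value (4.9 ± 0.5 μm/step)
is read as per-tip travel; both tips are driven symmetrically, so the
commanded separation closes at 9.8 μm/step. Frames are indexed
0..n_steps with step 0 the un-actuated state.

## Synthetic compression imagery

Per step the loaded-run equilibrium solves k·d = F(δ) with
δ = max(0, D − (s_cmd + 2d)) by bisection to a 1e−12 N residual (the
residual is strictly increasing in d, so the root is unique). The
reference run is the same actuation at E = 0.

Frames (default 384×128 px, 2 μm/px — pitch is a required config value
for real data, with no physical default claimed) stamp a smooth Gaussian
tip template (21 px, σ = 3 px, amplitude 0.75 over a 0.12 background) at
the true sub-pixel positions by bilinear splatting, the exact adjoint of
bilinear sampling, plus additive Gaussian pixel noise (default sd = 2%
of the dynamic range) clipped to [0, 1]. The same radially symmetric
template serves both tips, so tracked anchor separations equal physical
tip separations. What is *not* modeled: the real microscope's PSF,
illumination drift, tip-shape asymmetry, and spheroid silhouette —
passing tests demonstrate tracker/fit correctness on clean contact
imagery, not robustness to real optical artifacts.

## Tip tracking

Zero-mean normalized cross-correlation (illumination robust; the
original software's method is unnamed), searched in a ±10 px window
around the previous step's position; ties break to the smallest row,
then column. Sub-pixel refinement fits a separable 1-D parabola through
the peak and its axis neighbors (offset clamped to ±0.5 px). A best
score below 0.5 raises a tracking-lost error naming the step — half
correlation on a structured template means occlusion, and silent drift
is worse than failure. Measured accuracy on synthetic sequences:
≈0.02 px RMS at 2% noise (bound tested: <0.05 noiseless, <0.3 at 5%).

## TEM strip generator

A strip of length = spheroid diameter and height 100 μm (enough for
~5–7 cell rows; keeps panel-level density fluctuations small while the
strip stays desk-scale) is tessellated per region:

* cell count n = region_area·(1 − density)/mean_area;
* target areas drawn from a lognormal matched by moments to the preset
  mean/SD; dart-throwing places seeds with soft exclusion radii
  ∝ √area, larger cells first, best-candidate fallback so the count is
  always met;
* repulsion strength per region is set from the preset's area CV via a
  fixed four-point calibration curve (zero repulsion reproduces the
  Poisson-Voronoi CV ≈ 0.52; stronger repulsion regularizes the mosaic
  down to CV ≈ 0.3). This curve was measured once on the generator and
  is part of its design;
* a bounded Voronoi diagram (mirror-point reflection across the strip
  walls) assigns territories; each cell is its territory shrunk toward
  its centroid by a region-uniform factor, bisected so the polygon-exact
  uncovered fraction of the region's territory equals the preset space
  density (tolerance 1e−4).

An earlier variant that shrank each cell to its own drawn area was
rejected: it concentrates the interstitial space into cells whose draw
undershoots their territory, making panel-scale density wildly variable,
and cannot reach the day-20 inner 2.4% near-tiling at all. With the
uniform shrink the gaps are evenly distributed (as the micrographs show)
and the size law is carried by the territory distribution, which the
calibrated repulsion matches to the preset mean and SD.

Gap styles: `uniform` keeps a constant rim offset (day-20 inner — the
tightly packed core); `beaded` modulates the rim offset sinusoidally
along the boundary (relative amplitude 0.85, ≈6 μm bead spacing, random
phase) to imitate the bead-shaped interstitial spaces of young spheroids
and old rims. The nucleus is the cell polygon rescaled about its
centroid to a drawn nucleus/cell area ratio (clipped to [0.04, 0.8]) —
strictly inside by construction. Realized nucleus means run a few
percent low and their SDs ~20% compressed relative to the presets
(ratio clipping and decorrelation); cell-area statistics are the
calibrated quantities.

Panels: width 60 μm, 10% overlap ("sufficient overlap" is unquantified;
60 μm keeps the outermost edge-free panels inside the outer-25% region
at these diameters), last panel clamped to the strip end; first/last
panels carry the spheroid edge flag. Rendering paints gaps light (0.92),
cytoplasm 0.55, nuclei 0.25 at 2 px/μm.

## Morphometry protocol

* **Areas** by the shoelace formula (orientation-independent; validated
  against rasterization and shapely).
* **Complete-cell filter**: a cell counts only if its outline lies
  strictly inside a panel (touching the boundary disqualifies) and its
  whole nucleus is present inside the outline. Pooled statistics use
  cells complete in ≥1 panel, unique by id — pooling (not per-spheroid
  means) matches the printed group Ns.
* **Partition**: inner = centroid x ∈ [x_min + 0.25L, x_min + 0.75L)
  (half-open, boundary → inner), outer otherwise.
* **Density panels**: center = midpoint closest to the extent midpoint
  (ties → lower id); outer = outermost edge-free panel on each side (one
  per side; the protocol's "two outermost panels on both sides" is read
  as one per side). The outer density is their mean.
* **Space density** = 100 × uncovered pixels / total pixels after
  filling the clipped cell outlines, rasterized at 2 px/μm by
  pixel-center point sampling (matplotlib `Path.contains_points`).
  Pixel-center sampling is unbiased for arbitrarily thin gaps, which
  matters at the 2.4% day-20 core; boundary-inclusive scanline fills
  would systematically understate thin-gap densities. The full panel
  area is the denominator (no background exclusion). Density + covered
  fraction = 100 exactly at any resolution, by complementarity.
* Nuclei are *not* subtracted from cell areas (both are reported
  separately).

Known bias: with the strip spanning exactly the spheroid diameter, the
outermost edge-free panels can straddle the inner/outer boundary, so
reported outer densities blend a little core tissue (e.g. day-20 outer
≈10.2% vs preset 10.5%). Center panels sit fully inside the inner
region and are unbiased up to ±0.2 pp.

## Statistics

Welch's unequal-variance t-test (two-sided; Welch–Satterthwaite df),
implemented from the closed formulas with `scipy.stats.t` for the
distribution; a pooled Student's variant is available behind a flag.
The summary-statistics entry point reproduces, from the published group
summaries: moduli 260±100 vs 680±150 (n = 6 each, ± read as SD) →
t = −5.71, df = 8.71, p = 3.3e−4 (< 0.0005); day-20 inner-vs-outer
density 2.4±0.9 vs 10.5±1.6 (n = 3) → p = 3.9e−3 (< 0.005). The day-20
inner-vs-outer area summaries (224±106, n=26 vs 164±86, n=53; nuclei
71±43 vs 46±28) yield Welch p = 0.016 and 0.011 — significant at 0.05
but not at the 0.005 level; no standard two-sample test on those
summaries reaches 0.005, so the package reports the p-values it
computes. Significance marks follow the thresholds {p<0.005: \*,
p<0.001: \*\*}. No multiple-testing correction is applied.

## Determinism and problem sizes

Every random choice flows from an explicit integer seed through
`numpy.random.SeedSequence` spawning — no global state; `run-all` with a
fixed seed is hash-identical across invocations (SHA-256 manifest).

Problem sizes used by the tests and the acceptance script — six
compression runs per age (36 steps each), three full-size strips per age
(≈225–300 cells per strip), reduced 300×60 μm strips for unit tests —
were chosen as the study's own sample sizes where stated (n = 6
measurements, 3 spheroids per condition) and desk-scale otherwise.

## Limitations

* The mechanics arm's modulus recovery is a *consistency* test: the
  generator and the fit share the contact model by design. It validates
  the measurement chain (rendering → tracking → deflection → force →
  inversion), not the contact model itself.
* The tessellation is 2-D and ignores sectioning geometry (a real TEM
  slice samples a 3-D packing; cell-area laws here are the observed 2-D
  section statistics, not stereological reconstructions).
* Tracking assumes pure translation of a rigid tip pattern; rotation,
  scale change and multi-template tracking are out of scope.
* Printed ± spreads are interpreted as SDs throughout; if any were
  SEMs the generator presets would understate the population spread.
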