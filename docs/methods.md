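# Methods

## Capillary domains

A sampling frame is a rectangle (default square of area 0.145 mm²,
side ≈ 380.8 µm) with capillary positions in continuous µm
coordinates, origin bottom-left. The capillary domain of a capillary
is its Voronoi cell clipped to the frame — the tissue nearer to it
than to any other capillary. Cells are bounded by reflecting every
site across the four frame edges before Delaunay/Voronoi
construction; for any interior point the nearest site is then always
an original site, so the clipped cells of the original sites
partition the frame exactly. Areas are exact polygon areas, and the
partition property gives the internal check Σ areas = frame area
(relative error < 10⁻⁶ in tests). Degenerate inputs: a single
capillary owns the whole frame; collinear sites are handled by the
mirror construction; duplicate sites are rejected at input
validation because the tessellation needs distinct generators.

A brute-force raster oracle (`assign_pixels_bruteforce`) labels grid
cells by nearest capillary (ties to the lowest index, deterministic)
and is used only to cross-check polygon areas; at 0.25 µm resolution
the per-cell assignment noise leaves sub-0.5 % per-domain
discrepancies for ordinary domain sizes and sub-0.5 % aggregate
discrepancy over the frame in all tested regimes.

Domains touching the frame edge are flagged; statistics can exclude
them (`exclude_boundary_domains`) to reduce edge bias, but the
default includes all domains, preserving the exact identity
CDA_mean = frame_area/n = 1/CD.

## Supply indices

* CD = n_capillaries / frame area (mm⁻²).
* C:F uses a Gundersen counting frame: fibre profiles touching the
  left or bottom (forbidden) edges are excluded, right/top included,
  making the expected count unbiased by fibre size. CSA is the mean
  whole-polygon area of the counted fibres.
* CDA_mean is the arithmetic mean domain area; the CDA histogram
  defaults to 100 µm² bins over 0–3000 µm².
* logSD is the sample SD (n−1) of ln(CDA). The log base only
  rescales logSD by a constant; natural log is used. logSD is
  invariant under uniform spatial scaling and area-unit change, and
  vanishes (< 10⁻⁶) on the interior of a perfect hexagonal lattice.
* Core:cortex ratios divide each core index by its cortex
  counterpart; a single number per index summarising the
  whole-muscle phenotype shift (→ 1 as the compartments converge).
* Percent change = 100·(treated − control)/control, reported at full
  precision and rounded to the nearest integer.

## Oxygen transport model

Within each trapping region the tissue PO₂ field P (mmHg) satisfies

    D·α·∇²P = M₀·P/(P₅₀ + P)

with P = P_cap on the capillary lumen (cells within r_cap of the
site) and zero flux across the domain boundary — the trapping-region
assumption that each capillary supplies exactly its own domain. The
per-domain solves are independent by construction; a coupled
whole-frame solve is deliberately out of scope.

Parameters (all exposed; defaults are literature-magnitude values
for mammalian skeletal muscle, since modelled PO₂ levels depend on
them strongly):

| parameter | default | units | meaning |
|---|---|---|---|
| D | 2400 | µm²·s⁻¹ | tissue O₂ diffusivity |
| α | 3.89×10⁻⁵ | mL O₂·mL⁻¹·mmHg⁻¹ | O₂ solubility |
| M₀ (rest) | 1×10⁻⁴ | mL O₂·mL⁻¹·s⁻¹ | maximal consumption |
| M₀ (exercise) | 1.5×10⁻³ | mL O₂·mL⁻¹·s⁻¹ | high-demand preset |
| P₅₀ | 0.5 | mmHg | Michaelis constant |
| P_cap | 40 | mmHg | capillary-surface PO₂ |
| r_cap | 2.5 | µm | capillary radius |
| hypoxia threshold | 1 | mmHg | hypoxic-fraction cut-off |

Absolute PO₂ outputs should be read as model predictions under these
defaults, not as measured tissue values.

Discretisation: uniform Cartesian grid (default h = 1 µm; h ≤ r_cap
required), 5-point Laplacian, no-flux boundaries by reflective
stencil (a missing neighbour drops out of the stencil). The
Michaelis–Menten nonlinearity is resolved by Picard iteration with a
lagged denominator; each sweep is a direct sparse solve, and
iteration stops at max|ΔP| < 10⁻⁶ mmHg (cap 500 sweeps, error on
non-convergence). Negative intermediate values are clamped to zero
with a logged warning; converged solutions satisfy the maximum
principle 0 ≤ P ≤ P_cap.

Validation: in the zero-order limit (P₅₀ → 0, all P > 0) on a disc
of radius R the solution has the Krogh–Erlang closed form

    P(r) = P_cap + (M₀/(2Dα))·[(r² − r_cap²)/2 − R²·ln(r/r_cap)],

which the solver matches within 2 % at h = 0.5 µm; the formula
itself is cross-checked against an independent boundary-value ODE
solve. Grid convergence on the default synthetic frame at the
default (resting) parameters: halving h from 1 to 0.5 µm moves mean
PO₂ by ~0.06 % (at the exercise preset, where near-anoxic pockets
sharpen the field, the same halving moves it by ~1 %).

Known discretisation artifacts: at coarse h a clipped domain can
rasterise into disconnected fragments or into zero cells; fragments
disconnected from the lumen equilibrate near zero PO₂ (a few cells
at h = 2 µm), and empty domains are skipped with a logged warning.
Use h ≤ 1 µm when hypoxic fractions matter.

## Function metrics

Twitch peaks are local maxima above 10 % of the trace maximum
separated by at least half the inter-twitch interval, restricted to
the stimulation window. FI divides the mean of the last five twitch
peaks by the maximal mean of any five consecutive twitch peaks — the
"best five anywhere" reading is robust to delayed potentiation,
since the protocols do not guarantee the strongest twitches come
first. FI is reported both as a ratio and ×100; the ratio form is
the primary value. FI is invariant under positive scaling of the
whole trace. Peak detection is on raw twitch amplitudes (no
smoothing, no baseline subtraction beyond the height threshold).

Functional hyperaemia: vascular conductance = flow/pressure when
pressure is recorded (flow alone otherwise, logged); the relative
time course divides by the pre-stimulation baseline mean. The
hyperaemia ratio divides the peak of the 1-s moving-average-smoothed
flow during/after stimulation by the baseline mean flow; smoothing
keeps single noise spikes from defining the peak.

## Group statistics

One-way ANOVA uses the classical between/within decomposition with
Tukey HSD (studentized-range) pairwise p-values; for two groups F
equals t² of the pooled t-test exactly. Degenerate inputs (zero
total or within-group variance) are errors, not silent output.
Volcano tables use log2 fold change of raw group means (log-space
fold is available), the equal-variance Student's t-test (Welch
behind a flag), and Benjamini–Hochberg step-up FDR across compounds.
Compounds with a zero group mean are flagged, not dropped; zero
within-group variance with distinct means yields the smallest
representable p rather than 0. Significance defaults to P ≤ 0.05
(boundary inclusive); the FDR < 20 % screening threshold used for
heatmap-style summaries is exposed, not hard-coded. A plain
group-mean z-score table stands in for clustered-heatmap
presentation. The compound-identification filter accepts a feature
iff |Δmass| < 5 ppm, |ΔRT| < 30 s and isotope-pattern match > 90 %
(all strict).

## Synthetic data

The cross-section generator places fibre centres on a triangular
lattice scaled so the mean Voronoi (hexagonal) cell area equals the
requested fibre CSA, perturbs them with Gaussian jitter (SD =
jitter × lattice spacing), takes fibre outlines as the Voronoi
cells, and places capillaries at fibre-boundary triple points
(Voronoi vertices) — their anatomical position in the interstitium —
thinned by Bernoulli sampling so the expected count equals
CD × frame area. Densely capillarised phenotypes whose targets
exceed the triple-point supply draw the excess from fibre-edge
midpoints; truly unreachable targets are an error. All generators
are bit-reproducible given (spec, seed).

Preset phenotypes encode the control compartments: core CD
984 mm⁻², cortex CD 533 mm⁻², with mean fibre CSA derived from the
control capillary-to-fibre ratios as CSA ≈ C:F/CD (≈1870 and
≈2758 µm²), consistent with a core mean domain area near 1000 µm².
The default jitter of 0.3 yields logSD ≈ 0.5, a typical muscle
value. Fibre-area dispersion follows from the same jitter rather
than an independent CV parameter: Voronoi mosaics do not admit an
independently prescribed area CV without rejection sampling, and one
heterogeneity control suffices for the properties tested. Group
effect presets (CD/CSA multipliers per compartment, FI targets
0.47/0.58/0.75/0.82, metabolite folds such as kynurenic acid ×2 and
glutamate ×1.5 at 10 Hz) mirror the reported stimulated-group
changes.

Tension traces are raised-cosine twitch trains whose peak amplitudes
decay geometrically from 1.0 to the planted FI across the protocol,
with multiplicative Gaussian amplitude noise; the planted FI is
recovered within 0.02 at 2 % noise. Flow traces rise logistically
from baseline to baseline × peak_ratio with frequency-dependent
time-to-peak (4 Hz: end of the 3-min window; 10 Hz: mid-window;
40 Hz: after the window) and decay exponentially back; the planted
ratio is recovered within 5 % at 5 % noise. Metabolite intensities
are log-normal with ln-mean shifted by −σ²/2 so the *arithmetic*
group-mean ratio equals the planted fold; per-compound baselines
span orders of magnitude as in MS data.

What the generators do **not** emulate: fibre-type-specific
capillary affinity, spatially correlated angiogenesis (sprouting
near existing capillaries), intra-animal correlation across the five
regions of interest, heteroscedastic or missing MS intensities, and
batch effects. Passing round-trip tests therefore demonstrates the
correctness of the analysis chain under idealised conditions, not
robustness to every artefact of real histology or LC-MS data.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance
script each run in minutes on one CPU: 0.145 mm² frames (~70–200
capillaries), oxygen solves at h = 0.5–2 µm, 40-seed index
recoveries, 30-replicate metabolome summaries, 50 × 1000 null
calibration. All sizes are arguments and scale up directly.

## Open design choices

* Whether region-of-interest replicates are pooled or averaged per
  animal before group statistics is a flag (`per-animal mean` is the
  default posture in the pipeline, which generates per-animal
  frames).
* Edge handling of domain statistics (include vs exclude
  frame-touching domains) is configurable because published
  procedures rarely state it; including them keeps the 1/CD identity
  exact.
* The fold-change space (raw vs log means) and t-test variant
  (Student vs Welch) are flags with the conventional defaults.
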