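# Methods

This note documents the models, defaults and numerical choices behind the
package, what the synthetic-data generators emulate, and the limits of what
passing tests demonstrate about real data.

## Collagen displacement by PIV

Incremental fields are estimated between consecutive frames and summed per
grid point ("Eulerian" accumulation): the interrogation grid is fixed in the
laboratory frame, so the cumulative value at a grid point is the sum of the
pattern displacements observed there, not a material path integral. For
slowly contracting gels (per-step motion far below the window size) the two
agree to second order in the displacement gradient; at large cumulative
strain the Eulerian sum differs from a Lagrangian track by a term of order
|u|²/λ, with λ the decay length of the field.

Interrogation defaults: 32 px windows (power of two), 50% overlap, full
correlation search (±15 px). The correlation plane is the zero-padded linear
cross-correlation of mean-subtracted windows divided by the per-lag overlap
count. That division matters: the raw zero-padded correlation is weighted by
a triangle in the lag, which drags the three-point subpixel fit toward zero
by up to ~0.1 px; the unbiased cross-covariance removes the effect.
Subpixel localization is a three-point Gaussian fit per axis (parabolic
available), with negative-value guarding. Because the three-point fit is
unbiased only when the peak sits near the sampled lag, vectors whose
first-pass displacement exceeds 0.5 px are re-interrogated with symmetric
window offsets (both windows shifted by ±d/2, central-difference scheme, two
refinement passes by default); vectors below 0.5 px are left at the
first-pass estimate, because the fractional resampling of the refinement
would itself introduce interpolation bias at subpixel displacements.
Outliers are flagged by the normalized median test (threshold 2.0, ε =
0.1 px, 8-neighbour statistics) and replaced by the neighbour median;
windows with (near-)constant intensity are invalid and contribute zero to
the accumulation, which marks the point "imputed" from that step on.

The reduction is the mean of vector magnitudes (not the magnitude of the
mean vector) over the ROI — full field of view for spheroids, a centred
square of side 3 R₀ for explants — divided by R₀. The rate d|u|/dt is the
ordinary least-squares slope of the unnormalized mean magnitude against
time over the whole series; no fit window is applied.

## Synthetic collagen sequences and their ground truth

The generator advects an 8-bit speckle texture (uniform random dots at
density 0.08, 1 px Gaussian blur) by backward mapping with bilinear
interpolation: frame k samples frame 0 at x − u(x, t_k). Forward splatting
was rejected (holes). The displacement field is radial and inward with
magnitude rate·t·exp(−max(0, d − R₀)/λ): constant under the spheroid edge,
exponentially decaying beyond it. The decay length default is 100 µm — the
spatial decay is not constrained quantitatively by the assays this emulates,
so this is a free but fixed choice. Default geometry is a scaled-down
timelapse: 256×256 px at 4 µm/px, 241 frames every 0.25 h (60 h).

Ground truth is returned on the PIV grid as the *window-mean* of the
analytic field over each interrogation window, because the estimand of
window-correlation PIV is the mean displacement of the window content, not
the point value at the window centre; for the curved radial field the two
differ by several percent, which is a property of windowed estimation, not
an estimator error. Truth increments and cumulative fields are exactly
additive by construction.

What this generator does not emulate: collagen fibre structure and
alignment, strain stiffening feeding back on the displacement field,
out-of-plane motion, illumination drift, and acquisition noise beyond
additive Gaussian. Passing the oracle tests therefore demonstrates that the
estimator chain is accurate on trackable speckle under known advection — it
does not certify performance on degraded real micrographs.

## Spreading and escape

Segmentation of the fluorescent cell area: Otsu threshold, morphological
closing (disk radius 2 px), hole filling, then removal of components below
9 px. All surviving components count toward A — escaped single cells
included, which is what lets the equivalent-radius metric grow in the
single-cell escape regime. Hand-drawn boundary polygons (long CSV:
frame_index, vertex_x_um, vertex_y_um) can replace automatic segmentation
for explant-grade images. R_eq = √(A/π); the escape curve is R_eq/R_eq,0;
the rate d(A/A₀)/dt is the OLS slope over the full series.

The generator renders a central disk: constant for compact mode; radius
R₀√(1 + rate·t) for wetting. Evaporation keeps the core constant and emits
4 px-radius escaper dots on a golden-angle annulus packing (radially
increasing positions, ≥ 6 px rim gaps so segmentation cannot merge them) at
a spawn rate derived from the requested area rate, so that total covered
area tracks A₀(1 + rate·t) up to dot quantization. The true area series is
the pixel count of the rendered mask — exact by construction. High spawn
rates over long runs need a 384 px frame for annulus capacity; the generator
raises an error when an object would leave the frame. Real evaporation is
stochastic in position and timing and escapers change size and shape; the
deterministic packing emulates only the area budget and the angular
geometry.

## Active standard linear solid

Passive model: spring k_p and dashpot η in parallel (Kelvin–Voigt), in
series with spring k_s; creep compliance J(t) = 1/k_s +
(1/k_p)(1 − e^{−t·k_p/η}). The optical stress is a rectangular pulse of
height σ₀ during the stretch phase (trap phases are taken as zero-stress
baseline; the laser-power-to-stress calibration is out of scope, σ₀
defaults to 1.0 Pa). The active cortical response is an internal linear
stress ramping from 0 at onset t_on (measured from stretch start) to σ_int
at stretch end and held constant through the final trap phase (a switch-off
variant is exposed as `active_hold=False`); σ_eff = σ_ext − σ_a. The ramp
shape is a declared modelling choice: it keeps σ_int in pascals as the
single reported activity scalar and reproduces the delayed-contraction
phenomenology (deformation decreasing mid-stretch once σ_a exceeds σ₀).
Strain is evaluated by closed-form Boltzmann superposition of the two steps
and the ramp; a trapezoid-rule convolution oracle in the test suite agrees
to better than 10⁻⁵ relative.

Fitting: bounded nonlinear least squares (k ∈ [10⁻², 10³] Pa, η ∈ [10⁻²,
10³] Pa·s, σ_int ∈ [0, 10] Pa, t_on ∈ [0, t_stretch]) with five seeded
starts — the first from trace features (initial jump → k_s, late-stretch
level → k_p, early creep slope → η), the rest log-normal perturbations —
keeping the best residual. A fit is flagged non-converged when the
optimizer fails or a mechanical parameter pins at a box bound (degenerate
traces such as zero deformation, where σ_int ≈ σ₀ and stiffness are
confounded). Classification uses strict inequalities: non below 0.1 Pa,
high above 0.8 Pa, the boundary values themselves counting as moderate.
Cohort summaries report class percentages over converged fits (excluded
count alongside) and σ_int quartiles.

Identifiability sets the usable noise regime. At the protocol defaults
(30 Hz, 8 s), a linearized Cramér–Rao calculation at a non-contractile
parameter set gives sd(σ̂_int) ≈ 26·(strain noise sd) Pa: at noise 0.002
that is ≈ 0.05 Pa — half the width of the entire non-contractile band — so
class *fractions* of a cohort cannot be pinned to sampling precision at
that noise by any estimator, even though the median σ_int error (≈ 0.02 Pa)
is comfortably small. The cohort-classification study therefore generates
traces at strain noise 0.0005 (bound ≈ 0.013 Pa, far below the 0.1 Pa class
width), while the trace-level recovery study keeps noise 0.002. Cohort
generation draws σ_int uniformly within each class band (non [0, 0.1),
moderate [0.1, 0.8], high (0.8, 2.0]) with counts round(n·f) and the
remainder assigned to the largest fraction; mechanical parameters are drawn
uniformly from k_s, k_p ∈ [25, 60] Pa, η ∈ [30, 120] Pa·s, t_on ∈ [1, 3] s —
chosen so that 1 Pa produces the few-percent deformations typical of
suspended cells, with retardation times of one to a few seconds.

## Cell shape analysis

The shape index is implemented as p₀ = P₀/√A₀ — dimensionless, with the
isoperimetric minimum 2√π for a circle — which is the standard convention in
the vertex-model shape-index literature (a perimeter-over-area form would
carry units of 1/length). Perimeter and area come from the vertex chain and
the shoelace formula (via shapely); elongation and orientation from the
exact closed-form second moments of the polygon interior: aspect ratio
√(λ₁/λ₂), orientation the major-axis angle folded to (−π/2, π/2], flagged
unstable below an eigenvalue ratio of 1.05. Tangential alignment is
cos 2(θ_major − θ_tangent) with the tangent perpendicular to the radius at
the cell centroid. Contour roughness is std r(θ)/mean r(θ) over 360 uniform
rays for star-shaped contours (ray-boundary intersection via shapely);
non-star-shaped contours fall back to perimeter/convex-hull-perimeter − 1.
Deep-learning segmentation is out of scope: the module consumes outlines
(CSV/JSON vertex lists) produced elsewhere.

## AFM Hertz fitting

Spherical-indenter Hertz in the paraboloid regime, F =
(4/3)·E/(1−ν²)·√R·δ^{3/2}, valid since indentations (≈ 2 µm) are small
against the 22.5 µm bead radius. Working units µm/nN with E in Pa
(conversion factor 10⁻³ from Pa·µm² to nN). Poisson ratio defaults to 0.5
(incompressible gel convention) and is configurable; the synthetic generator
accepts ν ∈ [0, 0.5) and defaults to 0.45. Fits minimize residuals of
F = Hertz(δ − δ_c) jointly over log E and the contact offset δ_c on the
approach points below the 5 nN force cap, with δ_c initialized at the first
baseline-exceeding sample. Elasticity maps snap each positioned fit to its
grid cell (duplicates: last written wins, with a warning) and fill empty
cells from the nearest filled cell — deliberately no interpolation claims.

## Angular escape–displacement correlation

Displacement profile: mean |u| over valid grid points in the annulus
[R₀, R₀ + band] per angular bin (36 bins and band = R₀/2 by default; both
unconstrained by the assays and exposed as configuration). Escape profile:
per-bin maximum radial extent of the final cell mask minus the initial one —
the maximum-extent form is used for all masks since it is well defined for
detached escapers and non-star-shaped boundaries alike. Empty bins are
missing and excluded pairwise; Pearson r over the remaining bins, undefined
(NaN) under zero variance. The tuned-mixture check constructs anti-phase
profiles with a noise-to-signal standard-deviation ratio of √(1/0.36 − 1),
which makes the population correlation exactly −0.6; because a single
36-bin draw of r has a sampling standard error near 0.1, the recovered
value is reported as the mean over 50 seeded draws.

## Pipeline and reproducibility

The imaging pipeline composes PIV → accumulation → |u|/R₀ curve and rate
with segmentation → escape curve and rate, optionally the angular
correlation, from one YAML/JSON config; the stretcher pipeline maps a trace
directory to per-cell fits and a cohort summary. R₀ = "auto" uses the
equivalent radius of the first-frame segmented mask, and the explant ROI is
centred on that mask's centroid. Every run writes a manifest (package and
numpy versions, settings echo, SHA-256 settings hash, seed, timing); CSV
floats are written at fixed precision so identical configs and seeds yield
byte-identical outputs. Corrupt trace rows are skipped with a warning and
counted. Stages re-run from the previous stage's CSVs alone.

## Problem sizes

The validation studies run at: 241 frames of 256×256 px for the
displacement oracle and the three rate settings; 31 frames for spreading
(384 px frames for high-rate evaporation); 100 traces at noise 0.002 for
σ_int recovery and 446 at 0.0005 for cohort fractions; 50 seeds for noisy
Hertz recovery; 100/50 seeds for the correlation null and mixture. These
sizes were chosen so each study estimates its quantity with sampling error
well inside the tolerance it is checked against.

## Known limitations

* The Eulerian cumulative sum under-represents Lagrangian material motion
  once cumulative displacements become comparable to the field's decay
  length; the assays this targets stay well below that regime.
* σ_int and t_on are weakly identified for nearly passive cells (the ramp
  contribution vanishes); σ_int remains well estimated but t_on does not.
* The non-negativity of σ_int makes its estimator biased upward near zero;
  at classification-grade noise the bias is a few hundredths of a pascal.
* Segmentation constants (closing radius, minimum size) suit the synthetic
  rendering; real fluorescence data may need retuning, or external masks.
* The angular-correlation variant (band, bins, time window) is
  configuration, not a calibrated reproduction of any particular dataset.
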