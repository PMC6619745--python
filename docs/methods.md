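# Methods

This note documents the models, algorithms and numerical choices behind
`cmjfatigue`, and what the synthetic cohort does and does not emulate.

## Signal model and concentric-phase extraction

A countermovement-jump (CMJ) trial is a uniformly sampled vertical
ground-reaction-force trace F(t) (600 Hz by default). Bodyweight BW is the
mean force over the initial quiet-standing window (default 0.5 s); the
window's standard deviation is a quality gate (default limit 10 N — a ramp
or early movement raises an error rather than biasing the mass estimate).
Body mass is BW/g with g fixed at 9.81 m s⁻².

Velocity and displacement come from impulse–momentum integration,
a(t) = F/m − g, integrated by the cumulative trapezoid rule from the quiet
start (v = 0). No filtering is applied by default; the extraction functions
accept already-filtered traces if a user wants one.

The concentric phase is the interval of positive displacement change before
takeoff:

* **Takeoff** is the first sample below max(10 N, 2% BW). The propulsion
  peak is the force maximum *before* that sample — a landing spike later in
  the trace may exceed it and must not be mistaken for propulsion.
* **Onset** is the last upward zero-crossing of velocity before takeoff.
  A crossing must be preceded by a genuine countermovement (v < −2 cm s⁻¹),
  so integration drift during quiet standing can never spoof an onset. If
  no such crossing exists (no unweighting at all), a fallback anchor is
  used — the first sample after the unweighting minimum where force rises
  through 0.9 BW — and the segment is flagged.
* Onset and takeoff times are refined by linear interpolation of the
  velocity and threshold crossings, and the time of peak force by a
  parabola through the three samples around the discrete maximum, so the
  time features are not quantised to the sample grid (doubling the sample
  rate moves every feature by < 0.5%). Peak *values* are the discrete
  maxima (earliest sample on ties), which keeps the simulator → extraction
  loop exact.

Features per jump: rel_peak_force = max F / BW (unitless), rel_peak_power =
max(F·v)/m (W kg⁻¹), t_con (s), t_peak_force (s). Propulsion peaks are
counted as force maxima above BW with prominence ≥ 5% BW (the "double
peak" technique artefact).

## Stratified PCA

The four features at the eight measurement time points give 32 variables.
The sample unit is the jump repetition (jump k before training is paired
with jump k at every later time point), which is the only pairing that
yields 10 × 3 × 5 = 150 samples; session-mean pairing (30 samples) is
available as an option. Columns are centred and scaled (ddof = 1); rows
missing any cell are dropped with a logged count (no imputation); a
constant column is an error naming the column. The decomposition is the
SVD of the standardised matrix (via scikit-learn); eigenvector signs are
fixed by making each loading's largest-magnitude element positive. The
capability map groups PC-pair scores by athlete or workload with centroids
and dispersions.

## Functional PCA

Each concentric curve is expressed in bodyweight multiples on normalised
time [0, 1] (linear rescaling by t_con, which is kept as metadata; no
landmark registration). Smoothing minimises ‖y − Bc‖² + λ·cᵀPc with a
cubic b-spline basis (default 20 basis functions, open uniform knots) and
P = ∫B″B″ᵀ computed exactly by per-interval Gauss–Legendre quadrature.
λ is selected per curve by generalised cross-validation
(GCV = n·RSS/(n − tr H)²) on a log-spaced grid (1e−8…1e2, 21 points) and
the median across curves is applied to all, so every sample shares one
smoothing level.

The multivariate fPCA stacks the eight per-time-point coefficient vectors
of a sample, centres per slot, and eigendecomposes the coefficient
covariance in the metric of the block-diagonal basis Gram matrix via its
Cholesky factor; eigenfunctions (vectors of eight curves) are orthonormal
under the concatenated L² inner product, and signs make each PC's mean
slot-function integral positive. With an interpolating basis, zero penalty
and the grid-quadrature metric this reduces exactly to discrete PCA of the
grid values, which is the equivalence the tests exploit.

For the score heat map (samples × time points for one PC) the package uses
a **pooled** fPCA: all sample × time-point curves enter one univariate
decomposition around the grand mean curve, so every cell has its own score
and the mean fatigue time course remains visible in the columns. The
slot-centred multivariate construction removes each time point's mean
curve by design, which erases precisely the structure the heat map is
meant to show; this was confirmed empirically (no leading PC's slot
contributions clustered time points coherently) before the pooled variant
was adopted for clustering. Hierarchical clustering (Ward/Euclidean by
default; method configurable) is applied to the score matrix's rows
(samples) and columns (time points), with flat clusters at a configurable
cut. On the pooled decomposition of the default cohort, PC1 is the
amplitude/athlete mode, PC2 the main rate-of-force-development mode, and
PC3 the fatigue-contrast mode whose 3-cluster cut separates PRE–1 h from
24/48 h.

## Mixed-effects prediction

Eight configurations predict rel_peak_force at 6 h or 48 h from PC1/PC2 of
PCA or fPCA computed on all time points ("baseline") or on PRE/0/0.5 h only
("practical"). Practical scores come from re-running the decomposition on
the restricted window (12 variables, or 3 curve slots) — not from
projecting onto full-window components, because restricting the window
changes the components themselves.

The model is y = Xβ + Zb + ε with a random intercept per athlete,
b ~ N(0, σ²_b), ε ~ N(0, σ²_e), estimated by maximum likelihood (not REML):
for each variance ratio ψ = σ²_b/σ²_e the GLS β and σ̂²_e are closed-form
(block Woodbury), and a bounded 1-D search over log ψ (±15, xatol 1e−10)
maximises the profiled likelihood; the ψ = 0 boundary is checked
explicitly. Standard errors are the plug-in GLS ones. A design with one
observation per group is flagged unidentifiable rather than "solved".

Validation is leave-one-athlete-out: each fold refits on the remaining
athletes and predicts the held-out rows with fixed effects only (an unseen
athlete has no estimable intercept), pooling squared errors into one MSE.
R² is the squared Pearson correlation of observed and conditional fitted
values (fixed effects + BLUP intercepts); marginal/conditional
variance-decomposition pseudo-R² are reported alongside since the
definition is a convention. Likelihood-ratio comparisons use
LR = 2|Δloglik| with χ² df = the difference in fixed-effect counts;
fPCA-vs-PCA pairs have equal size and are not nested, so the LR is reported
descriptively with df 0, p = NaN and an explicit warning.

## The synthetic cohort

The generator emulates the study design end to end so that every stage is
testable without any data download. Per trial the force trace is built as
BW·(1 − dip + A·pulse), with ≥ 0.6 s quiet standing, a Gaussian
unweighting dip (35% BW, σ 60 ms), a propulsive pulse (σ 90 ms) whose
amplitude A is calibrated by a short fixed-point iteration so the realised
maximum equals the target relPeakF exactly, a terminal cosine ramp to zero
(takeoff), a ballistic flight phase whose duration matches the integrated
takeoff velocity (so height-from-velocity and height-from-flight-time agree
within integration error), and a 2.5 BW landing spike. A per-jump Bernoulli
draw replaces the pulse with a two-Gaussian mixture (the double-peak
artefact; amplitude ratio 0.8) paired with a shallower countermovement so
the concentric onset stays ahead of the first peak.

Fatigue follows the two-compartment curve
D(t) = d_w[α e^(−t/τ_m) + (1 − α)(t/τ_p)e^(1 − t/τ_p)] with α = 0.6,
τ_m = 1 h (the metabolic share is ~5% of its initial value by 3 h),
τ_p = 24 h (the neuromuscular share is still ≥ 70% of its peak at 48 h),
and workload scales d_w = 0.05/0.10/0.15 for low/moderate/high. The two
compartments drive different channels: the total decrement scales peak
force and dilates movement time by (1 + 0.5·D); the neuromuscular
component additionally widens the *rising* flank of the propulsive pulse
by (1 + 5·D_nm) — an impaired rate of force development, whose relative
impairment in fatigued athletes typically runs several-fold the peak-force
decrement. Without a shape channel distinct from amplitude, no analysis
could group the early time points together: the metabolic amplitude course
already differs strongly within PRE–1 h.

Athletes (defaults chosen once to mirror a recreational cohort): mass
~N(71, 12.4²) kg, unfatigued relPeakF 2.3 ± 0.3 BW (the athlete random
intercept), movement tempo ±10%, double-peak propensity U(0.05, 0.3), and
correlated log-normal fatigue-susceptibility gains (sd 0.35, ρ = 0.6)
multiplying the metabolic and neuromuscular components — the
individual-response heterogeneity that makes per-athlete prediction a
meaningful task. Jump-to-jump noise: white force noise (5 N), 2%
multiplicative amplitude noise, 2% timing jitter, 10 ms pulse-centre
jitter, 3% rising-flank variability. All randomness flows from one seed
through deterministically spawned per-trial substreams; a noise-free mode
supports exact closed-loop tests (extraction recovers injected relPeakF to
1e−6 BW).

What the generator does **not** emulate: eccentric-phase realism beyond
what onset detection needs, arm-swing/bar-load effects, within-set
fatigue across the five consecutive jumps, pacing effects across sessions,
and any physiological marker (e.g. lactate). Passing tests therefore
demonstrate the pipeline's correctness and its ability to recover this
generative structure at the study's size and noise level — not that real
CMJ data carry signals of exactly this strength.

## Numerical choices and degenerate inputs

* Integration: trapezoid everywhere; quadratures exact for the polynomial
  orders involved (Gauss–Legendre per knot span).
* Tie-breaks: earliest sample for discrete maxima; smallest λ on GCV ties;
  a force peak at the final concentric sample maps t_peak_force to t_con.
* Degenerate inputs: < 10 concentric samples, no flight phase, a takeoff
  threshold at/above the propulsion peak, zero-variance responses and
  all-identical fPCA samples raise or flag rather than returning numbers.
* Problem sizes: the default study (1200 traces) runs the full pipeline in
  a few seconds; the Monte-Carlo structure checks use 50 study replicates
  and the estimator-calibration checks 100–200 direct simulations, sizes
  chosen to keep the whole suite fast while leaving the binomial success
  criteria (≥ 70%, ≥ 80%, coverage within [88%, 99%]) well separated from
  their thresholds.

## Known limitations

* The concentric-onset definition needs a real countermovement; jumps
  without unweighting take the flagged 0.9 BW fallback.
* The pooled-fPCA heat map and the multivariate eigenfunctions answer
  slightly different questions (per-curve scores vs slot-restricted
  contributions); both are exposed, and the clustering accepts either.
* LOOCV prediction for unseen athletes uses fixed effects only; with
  strongly athlete-specific fatigue gains this is conservative by
  construction.
* The LRT between equally sized non-nested models has no χ² calibration;
  the package reports the raw ratio with a warning instead of a p-value.
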