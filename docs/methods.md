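# Methods

## Model

The simulator is a probabilistic cellular automaton on a periodic 2D
lattice (default spacing 12 μm, time step 2 ms).  Each unit is resting,
active, or refractory.  A resting unit activates in a step with probability

    1 − (1 − p_poiss) · (1 − p_stim) · (1 − p_trans)^m ,

where `m` is its number of active presynaptic neighbours, `p_poiss` the
homogeneous external Poisson drive, and `p_stim` an extra drive applied
only to a stimulated target cell (TC) during its stimulation window.  All
three sources are independent Bernoulli events; transmission is realised
edge-by-edge, not as an aggregate probability, so the update is a literal
superposition of independent per-edge trials.  An active unit transmits for
one step and then enters refractoriness for `refractory_steps` steps
(default 1).  With the chosen update order a unit is shielded from
re-activation for `refractory_steps + 1` activation phases after its spike;
an isolated unit under drive q therefore has stationary firing rate
q/(1+2q) per step and a fully driven unit fires every third step.  This
convention is the one consistent with the isolated-unit closed form used to
verify the kernel; it fixes the refractory ambiguity inherent in a 3-state
automaton.

Connectivity: every ordered pair (i, j) is connected independently with
probability `Pconn(r) = 0.05·exp(−r²/(2·100²)) + 0.03·exp(−r/290)` at the
torus distance r in μm.  The untruncated kernel has an analytic mean
out-degree of ≈130 at 12-μm spacing (`expected_out_degree`).  The reference
presets truncate connections beyond 240 μm, which gives a mean out-degree
of ≈43 — the degree at which the per-edge transmission probability
`p_trans = σ/k̄` matches the regime this model family is normally operated
in, and consistent with lateral connectivity between superficial pyramidal
cells being largely absent beyond ~200 μm.  The measured mean out-degree of
the realised graph, never the analytic value, enters `p_trans`.  Both
numbers are reported so the discrepancy between the kernel's analytic mass
and the truncated degree is visible rather than hidden.

Analysis is restricted to the central 38×38 block (1,444 units, 456×456
μm²) to avoid residual boundary artefacts; TCs are drawn from this block.

## Critical-point location

`find_critical_sigma` exploits that exactly at the critical point the
survival probability of a single-seed cascade decays as a power law,
P(t) ~ t^(−δ) with the 2+1-dimensional directed-percolation survival
exponent δ = 0.4505; below the transition the decay accelerates, above it
P(t) flattens.  A coarse σ grid brackets the point where the fitted log-log
decay slope crosses −δ, and the slope is then regressed against σ on two
successively finer grids and solved at −δ.  Two alternatives that look
natural are ill-conditioned here and were rejected after measurement: the
steepest point of the fixed-horizon survival curve P_T(σ) is smeared by
finite-horizon rounding of width ~T^(−1/ν∥) and sits on a curve rising as
(σ−σc)^β with β < 1, so its noise is large and its location biased; and the
zero of the log-log curvature of P(t) drifts systematically with the fit
window.  The horizon is kept short enough (400 steps by default) that
cascades stay smaller than the lattice — longer horizons let supercritical
cascades wrap the torus and self-collide, biasing the locator upward.  On
the reduced 120×120 preset the locator returns σc ≈ 1.02, a few 10⁻² above
1, as expected when propagation losses must be compensated; the exponent δ
is exposed as a parameter (mean-field graphs need δ = 1).

## Drive calibration and the drive-response exponent

`calibrate_poisson_drive` bisects log-drive against the measured stationary
rate, with a fixed seed per evaluation; each evaluation starts from a
weakly seeded state so a self-sustaining supercritical network is detected
as infeasible rather than silently bistable.  The reference baseline target
is **0.02 spikes per unit per 22-ms frame** (~0.9 Hz), matching the
near-zero mean window counts of resting superficial pyramidal cells.

The drive-response exponent γ is the least-squares log-log slope of
stationary mean active fraction against drive over
`DRIVE_GRID = 3·10⁻⁶…10⁻⁴` (8 log-spaced points, 2·10⁴ steps per point
after 4·10³ burn-in steps, averaged over independent sweep replicates).
The decade was chosen to sit inside the scaling window of the reduced
lattice: well below it, cascades are isolated and the response is linear in
drive regardless of σ (effective exponent → 1); well above it, the response
flattens toward saturation.  On the 120×120 preset this yields γ ≈ 1.00 at
σ = 0.5, γ ≈ 0.24–0.29 at the calibrated σc (2D directed-percolation
prediction 0.285), and γ ≈ 0.00 at σ = 1.2.

## Stimulation protocol and responder statistics

The protocol stimulates each TC for 50 steps (100 ms) with 2-s inter-trial
intervals, interleaving TCs in shuffled rounds; `p_stim` is bisected so the
mean TC spike count per 6-frame (132-ms) response window hits **5.0**
(with Poisson-like variability, slightly under 20% of trials then exceed 7
spikes per window, matching the stated range of evoked counts).  The
reference experiment pools **3 "experiments"** of 10 non-overlapping
central TCs × 150 trials on one calibrated network.

Windows (frames 0-based, half-open): response [f, f+6), baseline
[f−12, f−6), early baseline [f−18, f−12) for onset frame f.  Trials closer
than 18 frames to the recording start are dropped.  Outlier removal flags
(trial, cell) window counts above mean + 10 SD within each TC's trial
group; note that with all points included in the statistics the rule can
only fire when the trial count exceeds ~100 (the maximum standardised value
of n points is (n−1)/√n), so removal rates are tiny by construction.

The responder test compares the mean response window count to the baseline
distribution: z = (mean_resp − mean_base) / (SD_base·√(2/n)).  The √2
reflects that both window means are estimated from the same n trials; the
naive single-mean standard error would have null variance 2 and an
empirical type-I rate of ~8% at a nominal 2.5%.  With the two-sample form,
null fixtures reproduce the nominal rate (2.6% ± binomial error at
α = 2.5%; the small residual excess is the mean–variance coupling of count
data).  A one-tailed Welch t variant with Welch–Satterthwaite degrees of
freedom is available.  FDR correction offers Benjamini–Hochberg (default)
and Storey q-values (π₀ estimated at λ = 0.5); positive and negative tails
are adjusted separately.  Percentile rules (91st/25th/75th) use linear
interpolation; ties go to the lower subset.

Response scaling: trials are binned by integer TC spike count (1–7); the
class response per bin is the summed ("population") or per-cell mean
("per_neuron") spike count.  The slope of log mean response versus log
count is fitted by weighted least squares with delta-method errors on the
log bin means, which makes the 95% CI honest (coverage ≥ 90% on planted
fixtures across h ∈ {0.2, 0.3, 0.5, 1.0} with |bias| < 0.03).  In the
critical lattice the pooled population fit is fragile: single large
ongoing avalanches dominate bin means, and the pooled slope varies by
±0.2 between runs.  The reference experiment therefore reports the
**median of per-TC response-curve exponents** (30 curves over the pooled
experiments), which is markedly more stable, alongside the pooled fit.
Even so, the exponent depends steeply on the realised baseline rate —
≈ 0.25–0.36 when ongoing activity runs near 0.025 spikes/frame, rising
towards ≈ 0.5–0.7 when it runs near 0.018–0.021 — and because stationary
activity at criticality fluctuates slowly and strongly, the realised
baseline (and hence the measured exponent) varies between runs at fixed
drive.  At full scale, with an order of magnitude more pooled data, this
spread contracts; at the reduced preset the reported exponent should be
read with a ±0.1–0.2 run-to-run uncertainty.
End-to-end (classification then fit), detected-responder dilution by false
positives attenuates the recovered exponent by a few 10⁻²; the recovery
tests isolate the estimator with planted ground-truth tables.

Mean-matched Fano factors choose the stimulus window length (1–9 frames
from onset) minimising the normalised mean mismatch with baseline; cells
whose best mismatch exceeds 20% are excluded, and the uncorrected 6-frame
FF is reported alongside.

## Avalanche analysis

The population trace (TCs excluded whenever trials exist) is
soft-thresholded, pΘ(t) = max(p(t) − Θ, 0).  The threshold is selected per
coarse-graining factor k from the epoch-count curve N(Θ), which is fitted
with a log-normal shape; Θ* is the fitted log-location mapped back to the
count axis (e^μ; raw μ is exposed, and the argmax of N(Θ) is the flagged
fallback).  Coarse-graining at factor k produces k phase-offset series of
k-frame sums (incomplete tails dropped); avalanches are maximal positive
runs bounded by zeros (runs touching the series edges are discarded), with
size the summed thresholded counts and duration the run length, pooled
over phases.  Sizes are positive reals, not integers, because Θ* is
continuous.  The mean-size-versus-duration curve is fitted in log space
with the double power law with transition sharpness fixed at 4, free
(C, χsh, χlg, Φ), multi-start nonlinear least squares (start grid over
slopes and duration quantiles), unweighted by default.  Self-consistency:
refitting curves generated from the model recovers parameters with < 5%
median error at 5% log-noise.

## Decoding

Features are non-TC spike counts in a 6-frame window (offsettable); labels
are TC identities.  Filtered datasets drop trials whose TC fired no spike
in the response window and TCs active in fewer than half their trials.
Models: XGBoost (`hist`, default 500 trees, depth 6) and scikit-learn
random forest (500 trees); reference analyses at desk scale use 50–60
trees, which changes accuracies marginally on the fixtures.  Evaluation is
100× (tests use fewer) stratified 80/20 splits with per-class
precision/recall/F1.  Shapley attributions come from XGBoost's built-in
TreeSHAP on the training fold, ranked by mean |value| pooled over samples
and classes; the random forest falls back to impurity importances with a
warning.  Elimination removes the top feature(s) per iteration until one
remains, ties broken by cell index.  The exclusion-zone analysis retrains
after removing features within r of the evaluated TC (r = 0 reproduces the
full model exactly; removing every feature scores the chance level without
training); the critical radius is where the Gaussian-smoothed (σ = 1 grid
step) F1 curve first drops more than 3 SD below its mean rate of change.
Baseline pseudo-trials are non-overlapping 6-frame bins outside ±1 window
of any stimulation in which exactly one TC spiked, downsampled to the
stimulation class histogram.

## Synthetic recordings

Baselines are negative-binomial counts (mean per frame, Fano factor ≥ 1)
modulated by a per-cell log-normal AR(1) rate process whose scale is solved
from the exact log-normal autocovariance to hit a target adjacent-window
count correlation (default 0.2 at AR coefficient 0.9 per frame).  The
modulator adds burst variance beyond the nominal Fano factor — intentional,
as deconvolved cortical rasters are burst-dominated.  Planted positive
responders' response windows are driven at mean effect·(TC count)^h,
replacing ongoing activity (the planting that makes the total-count
scaling exponent equal h; additive planting is available but makes the
measured exponent a baseline-diluted mixture); negative responders are
decremented with a floor at zero, mimicking floor effects on sparse
baselines.  TC counts per trial are 1 + Poisson(mean − 1), guaranteeing the
1–7 bins are populated.  What the fixtures do not emulate: calcium-indicator
dynamics, deconvolution artefacts beyond count sparsity, spatial
correlation of baseline rates, and genuine avalanche spatio-temporal
structure (the lattice simulator provides that).  Passing fixture tests
therefore validates estimator calibration, not imaging-pipeline robustness.

## Reduced-scale presets and limitations

Reference problem sizes: 120×120 lattice for drive sweeps (2·10⁴ steps per
drive point), 150×150 for the stimulation experiment (3 × 10 TCs × 150
trials, 2-s ITI), 20 null-fixture seeds for the type-I rate.  At this scale
the direct-target composition statistic (fraction of a TC's direct targets
classified as positive responders) measures ≈75–88% per run — detection
power for single synapses grows with lattice size and trial count, so this
number is scale-sensitive and sits below what a full 300×300 run with
every-TC pooling yields.  Known limitations: no inhibitory units, one
refractory step by default, a single homogeneous drive, and avalanche
exponent estimation by least squares on binned curves (maximum-likelihood
tail fitting is deliberately out of scope; catalogs are exported for
external fitting).
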