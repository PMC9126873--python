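# Methods

## The circuit and its model

The system is a minimal cell-free genetic clock: a transcriptional
activator (a bacterial sigma factor, σ28) drives expression of a
repressor (TetR), which shuts down transcription of the activator.  The
delay required for sustained oscillation comes from explicitly modelling
the two mRNA species, giving four coupled ODEs for activator mRNA and
protein (r_a, a) and repressor mRNA and protein (r_h, h):

    dr_a/dt = α_a · 1/(1 + (h_eff/K_h)^n_h) − (δ + 1/τ_m,a) · r_a
    da/dt   = k_TL,a · r_a − δ · a
    dr_h/dt = α_h · 1/(1 + (K_a/a)^n_a)     − (δ + 1/τ_m,h) · r_h
    dh/dt   = k_TL,h · r_h − δ · h

Two reporter proteins (rep_a, rep_h) are translated from the same mRNAs
and diluted — they mimic the fluorescent co-reporters a microscope sees
and share k_TL and τ_m with their driving mRNA (no separate reporter
constants are available).  An exogenous input species x_in and a
reference dye decay by dilution only.

Forcing enters through the effective repressor concentration:
externally supplied repressor pools with the endogenous one
(h_eff = h + x_in), while an inducer is modelled as stoichiometric 1:1
sequestration (h_eff = max(h − x_in, 0)).  The sequestration law is the
simplest saturating choice, not a measured mechanism; it is an explicit
extension point.  Plots and classification always use the *endogenous*
repressor h, matching what a fluorescence channel reports.

Units are nM and seconds internally.  Parameter fields keep their
customary units (α in pM·s⁻¹ because transcription rates are set by
template concentrations in the pM·s⁻¹ range; τ_m in minutes) and are
converted at the boundary, which keeps configuration files readable and
confines conversion to two properties.

### Parameters

| symbol | meaning | free preset | forced preset |
|---|---|---|---|
| α | transcription rate | 3 pM/s (0.3–3 scanned) | 5 pM/s |
| K_a, K_h | Hill thresholds | 20 nM, 2 nM | same |
| n | Hill coefficient | 3 | 4 (scanned 3–8) |
| k_TL | translation rate | 0.02 s⁻¹ | same |
| τ_m | mRNA lifetime | 12 min | same |
| δ | dilution rate | from (R, t_int) | from λ |

α and δ are *control* parameters (experimentally tunable through
template concentration and refresh ratio); the rest are *system*
parameters fixed by molecular details.  The uniform constructor ties
activator and repressor kinetics (α_a = α_h etc.), the standard
simplification that preserves the qualitative dynamics.

## The semi-continuous reactor

The reactor replaces a fraction R of its volume with fresh reagents
every t_int = 15 min, which realises a dilution rate
δ = −ln(1−R)/t_int.  One simulated cycle is:

1. integrate the ODEs over t_int *without* the continuous −δ·x terms
   (removal physically happens only at feeds; keeping both would count
   dilution twice),
2. sample the interval-end state (one sample per cycle, like the
   recordings), then
3. apply the discrete map c ← c·(1−R) + c_in, where c_in carries the
   input amplitude A_in on every k-th feed (cycle index i with
   i mod k = 0) and the reference-dye spike on the same feeds.

A consequence of the map is that a non-reacting tracer decays exactly
geometrically, (1−R) per cycle, and the sampled trajectory converges to
the continuously diluted system as t_int shrinks at fixed δ; both are
asserted in tests.  The spike is applied at the feed that *ends* cycle
i, so it first appears in sample i+1 — the input rises instantly and
decays exponentially with rate δ, with dynamic range (1−R)^k ≈ 0.01 per
forcing period at R = 0.25, k = 16.

Integration uses a stiff-capable solver (LSODA) at rtol 1e−6,
atol 1e−9 nM; results are invariant to a 10× tolerance tightening at
plotting precision (tested).  The default initial condition is an empty
reactor filling with feed — self-starting and reproducible.  Reactor
fatigue (a slow decline of the realised R in long runs) is deliberately
*not* part of this ideal simulator; it lives in the synthetic-data layer
as a per-cycle R schedule.

## Timescales and the bifurcation parameter

The oscillator's intrinsic period is set by the dilution rate,
T ≈ C·π/δ with C close to one.  A zeitgeber with period
T_in = k·t_int then defines the single bifurcation parameter

    λ = T_in/T ≈ δ·T_in/π = k·(−ln(1−R))/π.

λ is tuned through R (continuously adjustable) at fixed T_in = 4 h,
because T_in itself can only change in steps of t_int.  The package
provides the exact inverse R(λ) = 1 − exp(−πλ/k).

## Analysis layer

**Period estimation.**  The primary estimator mean-subtracts the
signal, computes the biased autocorrelation normalized at lag 0 (the
biased form has the smoother tail), interpolates with a cubic spline on
a 32× finer lag grid, and returns the first local maximum after the
ACF's first dip (the dip guard rejects spline micro-wiggles near lag 0).
A damped-cosine fit to the ACF, optionally excluding the initial
transient, is the cross-check; the two agree within the period
uncertainty on simulated traces.  Every period carries a systematic
uncertainty σ_T = T / (number of signal maxima): records with few
complete cycles are dominated by the approach to the attractor.  The
proportionality constant 1 is this package's choice.

**Period–dilution scaling.**  C is measured by simulating 48-h
recordings from an empty reactor over R ∈ [0.1, 0.4], estimating each
period with the ACF estimator, and fitting T = C·π/δ by least squares
weighted with 1/σ_T².  The weighting matters: at α = 3 pM/s the lowest
dilution rates give damped traces with 2–4 maxima whose ACF period is
transient-inflated, and σ_T = T/n_maxima is precisely the uncertainty
model that discounts them.  The measured slope is C ≈ 1.03.

**Phase metrics.**  Sustained/damped/overdamped classification uses the
mean damping ratio γ = ⟨y_i/y_{i+1}⟩ of successive maxima (threshold
γ ≤ 1.05 for "sustained"; the tolerance is exposed), the normalized
equilibrium amplitude A_∞, and — when fewer than two maxima exist — an
exponential equilibration time τ_eq.  The first maximum is excluded
from γ whenever at least three exist, because a reactor filling from
empty always overshoots once; including the overshoot would label every
sustained trace "damped".  Maxima detection uses a prominence threshold
of 2% of the channel's dynamic range (exposed).

**Sensitivity.**  Each of the eleven parameters is perturbed by +30%
one at a time, the free oscillator re-simulated for 48 h and the period
re-estimated by ACF.  A δ-perturbation is realised through R so the
discrete map stays consistent.  δ dominates; the Hill coefficients and
mRNA lifetime are the only other relevant parameters.  Note the
measured ΔT/T for δ×1.3 is around −0.14, smaller in magnitude than the
−0.23 the ideal law T = π/δ would predict, because C itself drifts
slightly with δ; the ranking, not the ideal-law value, is the robust
statement.

**Rotation number.**  Maxima of the equilibrated endogenous-repressor
signal (first 500 cycles discarded) are detected; gaps longer than 20
cycles are filled at the forcing spacing with maxima *read off the
trace at the interpolated position*.  Period-doubled cycles can be
degenerate — one maximum of the underlying cycle appears only as a
shoulder — and the shoulder height is what distinguishes a degenerate
2-cycle from a 1-cycle, which a linear interpolation between the
(nearly equal) flanking peaks would erase.  The closure statistic
ΔM(k) is the largest absolute difference between the height sequence
and itself shifted by k, on heights normalized by their maximum
(max-norm is the strictest closure test and normalization makes the 0.1
threshold scale-free); m is the smallest k with ΔM(k) < 0.1, and a
trajectory with no closure for k ≤ 32 is classified chaotic.  For
*noisy* recordings the strict routine is inappropriate (the max
statistic grows with sample count under noise); `classify_trace(...,
noisy=True)` smooths with a 3-cycle moving average, enforces at most
one maximum per half forcing period, and aggregates ΔM by the mean.

**Instantaneous refresh ratio.**  R_t = 1 − I_{t+1}/I_t on the
reference-dye trace, for pairs whose first intensity exceeds 30% of the
trace maximum; pairs spanning a feed spike produce strongly negative
values and are flagged (plausibility band (−0.5, 1)) and excluded from
windowed means.

**Intensity normalization.**  Background-subtracted intensities are
scaled per reactor by a calibration-dye measurement and a one-point
1-μM reference, c = (I−B)/(I₀−B₀) · (I₀,ref−B₀,ref)/(I_ref−B_ref) ·
1 μM, making concentrations comparable across experiments.

**Hill transfer curves.**  Titrations are fit by least squares with
free scale and offset; 68% intervals come from the fit covariance.  A
fit is rejected as unidentifiable when the fitted curve sweeps less
than half of its own amplitude on the sampled grid (the plateau was
never observed) or when the covariance is degenerate.

## Bifurcation scans

The 1-D scan records equilibrated maxima of both protein channels per
λ; the 2-D scan classifies the rotation number over (n, λ).  Default
scan points run 500 equilibration plus 512 analysis cycles (600+ for
the 2-D scan; chaos verdicts need ≥ 32 maxima, i.e. ≥ 64 forcing
periods of analysis window when every period carries one maximum).
Along increasing λ the structure is 1 → 2 → 4 → … → 2 → 1: two period
doublings followed by halvings, with genuinely chaotic bands only at
higher Hill coefficients.  At n = 8 this implementation finds chaos
(no closure for k ≤ 32) for λ ≈ 1.50–1.54 and 1.58–1.60, interrupted
by periodic windows (a period-5 window covers λ ≈ 1.548–1.557, and
period-3 windows exist in the bands).  The *positions* of those windows
are numerically delicate: a ±4% change of the input amplitude at
λ = 1.5542 moves the classification between m = 4, 5, 8 and chaotic.
Band-level structure, not individual window boundaries, is the
reproducible statement.

## Synthetic data

The generator emulates what the microfluidic recordings deliver, so the
entire analysis chain can be exercised without instrument data:

- reporter and reference channels converted to raw intensities by the
  exact inverse of the normalization formula, with a synthetic
  calibration block carried alongside;
- multiplicative lognormal noise (unit mean, CV 0.05 by default) then
  additive background noise in intensity space — noise magnitudes are
  calibration knobs of this package, not measured values;
- late-run fatigue as a step (default) or linear ramp of R, one
  percentage point after 36 h;
- ground truth always emitted next to the raw data.

What the generator does *not* emulate: imaging artefacts (drift, focus,
bleaching), reagent-activity decay (which would lower α over time),
well-to-well variability, and any non-multiplicative noise structure.
Passing recovery tests therefore demonstrate the estimators' behaviour
under the stated noise model, not under every failure mode of a real
recording.

## Degenerate inputs and tie-breaks

Flat traces classify as overdamped with undefined τ_eq; monotone decays
raise a fixed-point-regime error in maxima detection rather than
returning an empty rotation result; `rotation_number` refuses to emit a
chaos verdict when too few maxima are available to test all shifts
(callers extend the run instead); a₀ = 0 in the activation Hill
function is defined by its limit 0 so empty reactors are valid states.

## Known limitations

- No linear stability / Hopf analysis; the phase diagram is empirical
  (simulate and classify).
- No Lyapunov exponents; chaos is operationally m > 32.
- No mechanistic competition of sigma factors for RNA polymerase; α is
  constant within a run.
- The inducer sequestration law is an assumption (see above).
- Exact chaotic-window positions depend on unidentifiable numerical
  details; see the bifurcation section.
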