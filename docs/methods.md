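# Methods

`riskcog` quantifies how a passenger's prefrontal cortex responds to
driving-scenario risk.  It couples two signal chains — a driving *risk
field* computed from vehicle kinematics, and cerebral oxygen exchange
(ΔCOE) computed from multichannel fNIRS — segments both into matched
low-risk and high-risk episodes, and asks, channel by channel, whether the
cortical response differs between them.  Because raw simulator recordings
are bulky and participant data cannot ship with a software package, a
synthetic co-simulator generates study-shaped data on demand; every
analysis in the test-suite and the acceptance script runs on data the
package itself generates at run time.

## Risk field

The risk of a traffic object (mass `M2`, separation `r`, speed `v2`,
angle `θ2` between the separation vector and the object's velocity) is
the scalar potential

    E = G · R2 · M2 / |r|^k1 · exp(k2 · v2 · cos θ2)

with defaults `G = 0.001`, `k1 = 1`, `k2 = 0.05 s/m`, `R2 = 1` (road
friction), `M2 = 1705 kg`.  The vector form of the field carries a unit
direction factor `r^k1 / |r^k1|`; only the magnitude enters any threshold
or mean comparison, so the module computes the scalar.  Speeds are SI
(m/s); ingest converts km/h.

A timestep is *high risk* iff `E > 0.05` (strict).  The high-risk episode
starts at the first crossing and lasts a per-scenario duration: 20 s for
lead-vehicle emergency braking (SAEB), 15 s for a left cut-in (LCI), 10 s
for a right cut-in (RCI), 6 s for a pedestrian crossing from the right
(RPCR).  An alternative convention that swaps the SAEB and RPCR durations
(6/15/10/20 in scenario order) circulates for the same design; both are
selectable via `risk.duration_mapping = "table1" | "methods"`, with
`table1` the default because the pedestrian scenario is the one whose
field completes its rise within ~6 s.  The *low-risk* episode is the
window of equal duration immediately preceding the crossing — the
standard event-locked pre-stimulus baseline; the source experiment never
states where its low-risk window sits, so this is a design choice of this
package (clipped at recording start with a truncation flag when the
pre-roll is short).  Pedestrians are scored with the same formula and the
default vehicle mass; `RiskParams.with_mass` supports a lighter override.

Per scenario the module reports `M_L`, `M_H` (episode means of `E`),
their difference `D_LH = M_H − M_L`, and a t-test between the per-event
episode means.

## fNIRS preprocessing

Inputs are per-channel ΔHbO/ΔHbR concentration changes (μmol/L, 8
channels by default, channel 8 over the anterior prefrontal cortex).
The cleaning chain, in order, is:

1. **Second-order polynomial detrending** — least-squares quadratic in
   time, removing slow drift; the residual is orthogonal to `{1, t, t²}`.
2. **TDDR** (temporal derivative distribution repair) — the signal is
   split at 0.5 Hz; the derivative of the low-frequency part is robustly
   re-weighted (Tukey biweight, c = 4.685, deviations standardised by
   1.4826×MAD around an iteratively re-estimated robust mean, iterated to
   a 1e-6 weight tolerance or 50 sweeps), re-integrated, and recombined
   with the untouched high-frequency part.  Two conventions deviate from
   the circulating reference code and are deliberate: the robust mean
   derivative is re-added before integration and the initial value is
   restored (the reference re-centres its output), so trends and offsets
   survive; and an exactly constant derivative short-circuits to the
   identity.  After removing that trend convention the output matches the
   reference implementation to numerical precision (asserted in tests
   against `mne`'s copy of the reference).  Two properties worth knowing:
   single-sample spikes live almost entirely above the 0.5 Hz split and
   are *not* repaired unless the split is disabled (it is skipped
   automatically when `fs ≤ 1 Hz`, or on request via `split_hz`); and the
   biweight shrinks inlier derivative deviations too (typical weight
   ≈ 0.9), so some amplitude shrinkage of the sub-0.5 Hz band is inherent
   to the procedure, roughly 20 % RMS for Gaussian-derivative signals —
   identical in the reference.
3. **Band-pass** 0.015–0.08 Hz, Butterworth order 4 applied
   forward-backward (zero phase, so episode onsets do not shift),
   removing residual drift, respiration (~0.3 Hz), cardiac pulsation
   (~1.1 Hz) and Mayer waves (~0.1 Hz).  The IIR family and order are not
   dictated by the experiment; Butterworth-4 zero-phase is standard fNIRS
   practice and both are config keys.
4. **Moving average** (optional, off by default) — centred, shrinking at
   the edges; used for road-vehicle recordings, window default 1 s.

Cleaned channels combine into the activity index
`ΔCOE = (ΔHbR − ΔHbO)/√2` (and companion `ΔCBV = (ΔHbO + ΔHbR)/√2`).
All steps except TDDR are linear, so ΔCOE commutes with the linear part
of the chain; TDDR is applied to the hemoglobin channels before the
index, and every output carries an ordered provenance record.

## Feature extraction

Each (channel, episode) ΔCOE segment is resampled to 64 points (linear
interpolation; episode durations differ across scenario types) and
reduced to one scalar two ways:

* **Mean value** — the segment's arithmetic mean (μmol/L).
* **K-SVD code** — a dictionary of K = 4 unit-norm atoms is learned per
  (scenario type, channel) on the pooled low+high segments by K-SVD:
  orthogonal matching pursuit with at most T0 = 1 nonzeros per segment,
  alternated with per-atom rank-1 SVD updates over each atom's support;
  unused atoms are re-seeded from the worst-represented segment.  The
  scalar feature is the single-atom OMP coefficient.  K, T0 and the
  15-iteration default are this package's choices (the source experiment
  states none); T0 = 1 makes the feature inherit the singular-vector sign
  ambiguity that is the known weakness of K-SVD features: two runs can
  return the same dictionary with an atom negated, flipping the feature's
  sign.  Atoms are therefore sign-canonicalised by default (first
  non-negligible coordinate positive); a test demonstrates the flip with
  canonicalisation off.  Because of the ambiguity, only |T| is
  interpretable for K-SVD features.

## Statistics

* **Episode t-value** — computed on (high − low) so positive values mean
  a larger response under high risk.  Default is a paired t across
  scenario instances (episodes come in within-instance pairs by
  construction); pooled-variance and Welch independent-sample variants
  are config options.  Zero-variance differences yield a flagged ±∞
  sentinel rather than an exception.
* **Wilcoxon signed-rank Z** (small road-vehicle samples) — SPSS
  convention: zero differences dropped, average ranks for ties,
  `W = min(W⁺, W⁻)`, `Z = (W − n(n+1)/4) / √(n(n+1)(2n+1)/24 − Σ(t³−t)/48)`,
  no continuity correction; `Z ≤ 0` by construction.  For n ≤ 10 the
  normal approximation's moments are validated by exhaustive enumeration
  of all sign patterns.
* **Gaussian GLM** (identity link, maximum likelihood) — coefficients by
  least squares, scale = RSS/n (the ML estimate, not RSS/(n−p)),
  `SE = √(scale·(XᵀX)⁻¹)`, Wald χ² = (B/SE)² with 1 df, 95 % Wald CI =
  B ± 1.959964·SE.  Three model directions are supported — ΔCOE on risk,
  risk on ΔCOE, and intercept-only — because the published parameter
  table is literally an intercept-only fit of the risk field and it
  cannot be determined whether a slope was fitted and omitted; the
  report labels which was run.  No multiple-testing correction is applied
  across channels by default (matching the source analysis); Bonferroni
  and Benjamini–Hochberg columns are available as options.
* **Grouped summaries** — five-number boxplot statistics per sex /
  driving-experience group and risk class, with per-group low-vs-high
  p-values; singleton groups are flagged, empty groups omitted.

No significance threshold is hard-coded anywhere; exact p-values are
reported.

## Synthetic co-simulator

Kinematics are minimal constant-rate phase models, sufficient to drive
the risk formula, with the ego vehicle at 70 km/h on a straight
three-lane road: a lead vehicle 150 m ahead braking at 5 m/s² (ego
braking to stop 10 m behind); adjacent-lane vehicles 100 m ahead slowing
to 55 km/h while cutting in at 0.6–1 m/s lateral speed (ego settling to
follow at ~28 m); a pedestrian stepping off the right kerb at 1.4 m/s,
placed so that hard braking (4 m/s²) from the event moment stops the ego
10 m short.  Distances and speeds get mild seeded jitter across
instances; every generated instance is validated to cross the 0.05
threshold (and filler "no event" scenarios to never cross it), and the
generated episode means satisfy `M_L < 0.05 < M_H` by construction.
Sessions mirror the study design: 20 participants × 12 segments × 24
scenarios (14 SAEB + 28 LCI + 25 RCI + 33 RPCR events and 188 event-free
fillers per participant, i.e. type totals 280/560/500/660 across
participants), a 1000 m event-free lead-in per segment, and seeded random
ordering.

Hemodynamics: per channel, ΔHbO/ΔHbR = ±(evoked response) + quadratic
drift + cardiac (1.1 Hz) + respiratory (0.3 Hz) + Mayer (0.1 Hz)
sinusoids + Poisson motion artifacts (single-sample spikes and baseline
steps) + white noise, at 10 Hz (the device class samples near 10 Hz; the
rate is a config key, never hard-coded).  The evoked response is the
high-risk boxcar convolved with a canonical double-gamma HRF (peak 6 s,
undershoot 16 s) scaled by a per-channel amplitude — default 0.12 μmol/L
on channel 8 and 0.04 elsewhere, expressed directly in ΔCOE units and
split 2:1 between ΔHbO and ΔHbR.  The sign convention defaults to a
*positive* ΔCOE–risk coupling, reproducing the empirical finding the
package is built around; the physiologically more common opposite sign is
one switch away (`coupling_sign = -1`) since the origin of the positive
coupling is an open physiological question on which the generator takes
no position.  Every recording ships with a ground-truth ledger (injected
amplitudes, artifact times, noise parameters) for parameter-recovery
tests.

What the generator does *not* emulate: optode-skin coupling changes,
systemic physiology correlated with the stimulus (a serious real-world
confound), inter-channel correlated noise, habituation across a session,
and individual HRF variability.  Passing recovery tests therefore show
the pipeline is correct and sensitive under its stated noise model — not
that the empirical effect would replicate in new participants.

## Problem sizes

Tests and the acceptance checks run deliberately small instances chosen
as representative: sessions of 12 scenario events (3 per type, ~10 min of
simulated recording at 10 Hz), 20 seeded sessions for the
parameter-recovery property (channel 8 must win the mean-feature T
contest and the ΔCOE–risk slope must be positive in ≥ 90 % of sessions —
both pass at 95–100 %), and exhaustive 2⁷ enumeration for the Wilcoxon
oracle.  The study-scale session plan (20 × 12 × 24) is exercised at the
bookkeeping level; generating its full recordings is possible with the
same code but unnecessary for any assertion made here.

## Numerical choices and degenerate inputs

Half-open spans `[start, end)` everywhere; timestamps in seconds from
recording start; channels 1-based.  Strict `>` at the risk threshold (a
sample exactly at 0.05 is low risk).  Zero separation distance raises a
domain error naming the timestep.  Zero-variance contrasts are flagged
degenerate rather than raised.  Sample-rate uniformity is validated at
±1 % on CSV ingest.  K-SVD tie-breaks follow `argmax` order; its RNG
touches only initial-atom choice.  All randomness flows from explicit
seeds; identical spec + seed reproduces every output byte.
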