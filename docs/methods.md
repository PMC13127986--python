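# Methods

This note documents the models, estimators, defaults and design decisions
behind `neurocarousel`, in the order data flows through the package.

## Signal model of the synthetic LFP

One channel is

    x(t) = A_θ sin(φ_θ(t) + π/2)
         + Σ_g  A_g · (1 + κ_g cos(φ_θ(t) − ψ_g)) / √(1 + κ_g²/2) · sin(2π f_g t)
         + pink noise (σ_pink)
         + Σ_k  a_k sin(2π·50k·t + φ_k)

with φ_θ(t) = 2π f_θ t + W(t) − π/2 the analytic phase of the theta
component (W is an optional phase random walk, see below). Each gamma
oscillator's instantaneous amplitude is a cosine function of theta phase;
κ ∈ [0, 1] is the programmed coupling strength and ψ the preferred phase.

*Envelope normalisation.* The modulated envelope is divided by its RMS
√(1 + κ²/2) rather than by its peak (1 + κ). This makes mean gamma band
power *exactly* independent of κ, so coupling manipulations and power
manipulations are orthogonal by construction — the property needed to
emulate dissociated findings (a power change without a coupling change and
vice versa). Peak normalisation would leak a +66 % power change into a
κ: 0.6→0.15 manipulation.

*Pink noise.* Background noise is white noise spectrally shaped to a 1/f
**power** profile above 1 Hz (flat below, matching a 1 Hz hardware
high-pass), then scaled to standard deviation `pink_sigma`. A steeper 1/f²
profile would leave essentially no gamma-band noise and make every PLV
saturate near 1.

*Theta phase diffusion* (`theta_jitter`, rad²/s, default 0). Real theta is
not a pure tone; its phase wanders. With jitter enabled the modulator is
aperiodic, which matters for shuffle surrogates: a circular shift of a
strictly periodic envelope only rotates the preferred phase and cannot
lower the PLV, so the shuffle-null diagnostic is only meaningful on
jittered (or real) signals. All coupling-recovery oracles use the default 0.

*Defaults* (chosen once from a design-time sweep, not re-tuned): fs 2000 Hz,
f_θ 7 Hz, A_θ 50 µV, f_γ 75 Hz, A_γ 15 µV, σ_pink 30 µV, line amplitudes
(5, 2, 1) µV at 50/100/150 Hz. These put PLV(κ) at ≈ 0.07 / 0.48 / 0.75 /
0.85 / 0.89 over κ ∈ {0, .25, .5, .75, 1} for 30 s epochs — graded, and in
the range empirical theta–gamma PLVs occupy, rather than saturated.

## Cohort model

`CohortSpec` draws one lognormal scale per animal (`between_sigma`, default
0.2) applied to all amplitudes — stable individual differences, shared
between that animal's baseline and post epochs — plus an independent
per-epoch lognormal amplitude jitter (`within_sigma`, default 0.08).
The within-animal term matters: between-animal scale cancels exactly in
percent-of-baseline normalisation, so without epoch-to-epoch drift the null
variance of the percent change would be measurement noise only and every
group test would be degenerate. Group effect multipliers
(`low_gamma_power`, `high_gamma_power` on power; `kappa` on coupling) apply
only in the post epoch. Animals get 2 channels (electrodes) with shared
parameters and independent noise; per-animal metrics average the
electrodes.

Epochs default to 60 s at 2000 Hz. The emulated protocol uses 10-min
analysis windows; 60 s keeps a full two-group, n=7 cohort replica at a few
seconds of compute while still containing ~420 theta cycles, far above the
PLV estimator's stability threshold. PSD/PLV estimates at 60 s are noisier
than at 10 min, which the power analysis absorbs.

*Replica effect sizes.* The emulated study reports only significance
statements, not effect magnitudes, so the replica cohort's multipliers are
free design parameters: κ ×0.25 and low-gamma power ×2.0 in the treated
group. Note that a power multiplier acts on the *oscillation*, while band
power also contains the pink-noise floor: ×2.0 realises ≈ +70 %
baseline-normalised change in the 30–55 Hz band mean. These defaults give
near-complete detection power at n = 7/group, i.e. they encode a clearly
present effect, as in the emulated findings.

## Locomotion model

`generate_walk` integrates an Ornstein–Uhlenbeck velocity process
(persistence time τ, default 1 s) whose stationary speed distribution has
the requested mean (per-component σ_v = mean_speed/√(π/2)), reflected at
the enclosure boundary (square box or disc). The avoidance agent adds a
tangential drift of magnitude `avoidance_gain` (cm/s²) away from the
sector center whenever the agent is inside the sector dilated by 15°;
entrances fall monotonically with the gain. Degenerate modes provide exact
geometric oracles: a point fixed in the room, and a point fixed on the
rotating disc (which in room coordinates traces a circle of circumference
2πr per revolution and sweeps the room-stable sector once per revolution,
occupying it for 1/6 of the period).

What the generators do **not** emulate: sharp-wave or spindle morphology,
cross-channel volume conduction, movement artifacts, non-stationary drug
pharmacokinetics within an epoch, thigmotaxis, grooming/rearing postures,
or any biophysics of NMDA-receptor antagonism. Passing tests therefore
demonstrate that the *estimators* recover programmed ground truth under
realistic noise — not that real recordings satisfy the model.

## Preprocessing

- **Notch cascade**: second-order IIR notches at 50k Hz, k = 1..5 (up to
  250 Hz), quality factor 30 (≈1.7 Hz bandwidth at 50 Hz). The narrow
  notch preserves the 30–55 and 55–100 Hz analysis bands (≤5 % change at
  40 Hz).
- **Band-pass**: 4th-order Butterworth.
- Both are applied **zero-phase** (forward–backward, `sosfiltfilt`), even
  though a causal biquad would be the literal hardware analogue: PAC phase
  estimates must not inherit a filter phase shift. Whether the original
  analysis was causal is unknowable from the protocol; zero-phase is the
  defensible choice for phase metrics.
- A 1 s **edge margin** is recorded in metadata and trimmed before any
  phase/amplitude statistic (filter transients decay below phase-relevant
  levels well within 1 s; the stricter 10⁻⁶-RMS commutation property needs
  ≈2 s).
- Windows are half-open [start, end); sample count = round((end−start)·fs).

## Spectral estimation

Welch PSD with 2 s Hanning segments and 50 % overlap. Segment length is a
free parameter in the emulated protocol; 2 s gives 0.5 Hz resolution
(resolving the 4 Hz theta edge) and ≥ 59 segments per minute. Density
scaling is variance-preserving (Parseval: ∫S df = var within 5 % for
stationary noise, exactly a²/2 for a sine). Band power is the mean density
over bins with f_lo ≤ f ≤ f_hi, **edges inclusive**. Percent change is the
signed convention (0 = no change); the ratio convention (100 = no change)
is available as `BaselineChange.as_ratio`. Spectrograms: 1 s Hamming, 75 %
overlap, columns at window centers, 30–100 Hz.

## PAC estimation

Pipeline per channel: band-pass (phase band) → Hilbert phase; band-pass
(amplitude band) → Hilbert envelope → **band-pass the envelope in the phase
band** → Hilbert phase; PLV and preferred phase from the phase differences
(phase-band phase minus envelope phase, so the preferred phase equals the
ψ₀ of the generator). Filtering the envelope before its Hilbert transform
is necessary: the raw envelope has a large DC offset which makes its
instantaneous phase ill-defined. Epochs must retain ≥ 10 phase-band cycles
after edge trimming. PAC is computed over the whole window (no
sub-segmenting); a circular-shift surrogate (`shuffle_null`) is provided as
an optional diagnostic, with the periodicity caveat above. PLV is invariant
to amplitude scaling of either band by construction.

## Behavior metrics

- **Frames**: arena→room rotates by +θ(t) = ±2πt/60 s (counterclockwise by
  default; the rotation direction is configurable since the protocol does
  not fix it). Radii are preserved exactly; round trips are identities.
- **Entrances**: maximal in-sector intervals of the room-frame azimuth
  (sector center ± 30°); `min_outside` hysteresis (default 0 s) merges
  re-entries separated by brief tracking exits.
- **Shocks**: one at entrance onset plus one per 900 ms of continuous
  occupancy — a dwell d delivers one shock per k ≥ 0 with 0.9k < d. Shock
  pulses are treated as instantaneous events.
- **Distances**: Euclidean steps after optional median smoothing, ignoring
  steps below `jitter_floor`; defaults (no smoothing, floor 0) change
  nothing. "Distance in the arena" is reported in the **arena frame**
  (locomotion net of passive disc transport) with the room-frame value
  alongside, since the protocol does not state the frame; the two differ by
  at most 2πR per revolution.
- **Center zone**: the concentric square of 25 % of the floor area (35 cm
  side in the 70 cm box). The protocol never defines "center"; 25 % is the
  common convention and the fraction is configurable.
- **Binning**: half-open bins; steps/events assigned by start time, so bin
  sums reproduce session totals exactly. A sample owns the interval to the
  next sample (the last sample owns the preceding interval's width).

## Statistics

Shapiro–Wilk at α = 0.05 per group gates every metric: all groups normal →
one-way ANOVA with Tukey HSD (studentized range with Tukey–Kramer
correction for unequal n); otherwise Kruskal–Wallis (tie-corrected H) with
Dunn's z tests. Dunn p-values are Bonferroni-adjusted over all pairs by
default (Holm available) — the emulated software's exact convention is not
documented, and Bonferroni is the conservative default. Post hoc tests run
only when the omnibus p < 0.05. The chain's empirical type-I error at
group sizes 7/5/5 stays within [0.03, 0.07] of the nominal 0.05.

The two-way mixed ANOVA (`rm_anova_balanced`) computes the group, day and
interaction F tests from the balanced-design sums of squares, **without**
sphericity correction, and refuses incomplete designs (pointing to proper
mixed-model tools). Degenerate inputs are defined: zero-variance numerator
→ F = 0, p = 1; zero error term with a non-zero effect → F = ∞, p = 0.
Constant groups in the normality gate raise (W is undefined), as does a
zero-variance input to `correlate`. SEM uses the n−1 sample standard
deviation and is NaN for n = 1.

## Problem sizes used in verification

Parseval: 20 s noise / 10 s sine fixtures. Filter contracts: 10 s sines.
PAC: 20 s noise-free, 60 s uncoupled nulls, 20 seeds × 5 κ values × 30 s
for monotonicity. Behavior: 20-min disc-fixed session at 20 Hz sampling.
Statistics: 1000 null simulations at n = 7/5/5. Replica experiment: 50
effect cohorts and 50 null cohorts, 7 + 7 animals × two 60 s epochs × 2
channels each.

## Known limitations

- The PSD/PLV verification rests on synthetic signals whose coupling is
  sinusoidal in theta phase; estimator behavior under asymmetric or
  multi-modal coupling is untested.
- The shuffle-null surrogate is uninformative for strictly periodic
  modulators (see above).
- No artifact rejection (chewing, movement) and no adaptive line-noise
  removal; heavily contaminated epochs are the user's responsibility.
- `rm_anova_balanced` deliberately omits sphericity corrections and
  unbalanced mixed-effects fitting.
- EDF reading requires `mne` and is lightly exercised; CSV/flat-binary plus
  JSON sidecar is the first-class interchange format.
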