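# Methods

## The indices

**nMxa.** Cerebral autoregulation is probed through spontaneous slow waves
(0.005–0.05 Hz) present in both arterial blood pressure (ABP) and middle-
cerebral-artery blood-flow velocity (FV). Both channels are reduced to
non-overlapping 10-s block means; block averaging low-passes the series at
roughly 0.05 Hz, suppressing cardiac (~1 Hz) and respiratory (~0.2–0.3 Hz)
content while retaining the slow-wave band — this is the established
Mx-family implementation, and we use it instead of an explicit band-pass
filter. Within each 5-min (300 s, 30 blocks) moving window, stepped by one
block (10 s), the Pearson correlation of the paired valid blocks is
computed. The per-side summary nMxa is the arithmetic mean of the window
correlations; the combined index is the unweighted mean of the available
sides. A summary strictly greater than 0.4 is classified as impaired
autoregulation. Windows with fewer than 25 of 30 valid block pairs
(tolerating ~17% masked data) or zero variance on either side are omitted
with a logged reason; omission, not zero-scoring, because Pearson r is
undefined there. nMxa is reported as the mean over the recording, with a
median variant unnecessary for the synthetic studies here. The index is
invariant to affine rescaling of either channel, so measurement units do not
matter.

**THRR.** The transient hyperaemic response test applies a brief (5–7 s)
unilateral carotid compression; adequate compression drops ipsilateral
systolic FV by more than 30%. On release, intact autoregulation (which
dilated the distal bed during the pressure drop) produces a transient
hyperaemic overshoot. Following the clinical definition, the first
post-release systolic peak is ignored and the mean of the next three is
divided by the resting baseline: the mean systolic FV of the five beats
immediately preceding compression onset (five beats ≈ 4–6 s of rest; the
clinical definition says "resting flow velocities" without a count). A ratio
of at least 1.10 — inclusive, equivalent to a >9% flow increase — is
classified as preserved autoregulation. Episodes carry four QC flags
(`drop_ok`: nadir ≤ 70% of baseline; `duration_ok`: 5–7 s with ±1 s
tolerance; `spacing_ok`: ≥ ~60 s after the previous episode; `signal_ok`:
all required beats present and unmasked). Episodes failing any flag are
excluded from the per-side session mean but reported in the audit trail,
since in practice missing THRR values trace to poor compression quality and
the QC must be explicit.

## Preprocessing

Artefact masking unions three rules with any pre-existing mask: physiological
range (ABP outside [20, 300] mmHg; FV outside (0, 150] cm/s, zero flow being
a lost-signal reading; the limits bracket physiology with wide margins and
are deliberately far from the 55 ± 12 cm/s plausibility range used at the
probe), flatline runs of at least 2 s with zero sample-to-sample variance,
and isolated spikes more than 5 robust SDs (1.4826·MAD) from a 1-s rolling
median. No interpolation is performed across masked gaps; invalid samples
simply drop out of block means and beats, so enlarging a mask can only
reduce the number of valid blocks and beats (a tested invariant).

Beat detection finds systolic peaks as local maxima with prominence at least
25% of the locally estimated pulse amplitude (95th–5th percentile over 10-s
segments, interpolated) and a 0.3-s refractory period; the local amplitude
reference lets detection track the ~35% amplitude drop during carotid
compression. Diastolic value and per-beat mean are taken over the
peak-to-peak interval; beats overlapping masked samples or with intervals
outside 0.3–2.0 s are flagged invalid.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
vascular biophysics (no Windkessel/autoregulation-index dynamics, no CO₂
reactivity, no ICP):

- ABP = mean (90 mmHg) + configured slow sinusoids + a cardiac pulse train.
  The pulse template is a gamma-like shape `u² exp(2(1−u))`, `u = phase/0.2`:
  fast systolic upstroke peaking 20% into the beat, slow diastolic decay —
  asymmetric so beat detectors face realistic morphology. Each beat is
  zero-mean (the template's continuous mean is subtracted), so the pulse
  train adds pulsatility without shifting channel means. Beat intervals are
  60/HR (HR 70 bpm) with i.i.d. 3% fractional Gaussian jitter, shared by all
  channels (one heart).
- FV (each side) = mean (55 cm/s) + g·(55/90)·(ABP slow waves)
  + (1−g)·(intrinsic slow sinusoid) + pulse train (amplitude 30 cm/s)
  + white noise (SD 2 cm/s). The coupling gain g ∈ [0, 1] is the ground
  truth: g=1 is fully pressure-passive (impaired), g=0 fully decoupled
  (ideal autoregulation). The (55/90) scaling keeps g interpretable as
  fractional pressure-passivity in dimensionally consistent units. The
  intrinsic sinusoid has amplitude 2.5 cm/s and a seeded random frequency
  in 0.008–0.045 Hz and phase, independent per side.
- One global seed expands into fixed named substreams (heart rate, each FV
  side, artefacts, THRT), so toggling one stochastic component leaves the
  others bit-identical. Identical configs reproduce bit-identical output.
- The respiratory component is off by default (no amplitude is established
  for this protocol); it can be enabled via `resp_wave`.

**Expected correlation.** At block level each sinusoid of frequency f is
attenuated by sinc(f·10 s) and white noise by √1250, giving the closed form

    r = g·σa / sqrt(g²·σa² + (1−g)²·σi² + σn²)

with σa the scaled, attenuated ABP slow-wave SD, σi the attenuated intrinsic
SD and σn the residual noise SD. Note σi must be the block-level SD: at
0.045 Hz the 10-s block attenuation is already sinc(0.45) ≈ 0.70, and
ignoring it biases the prediction low by up to ~0.06. Tests verify the
generator against this form to within 0.03.

**Default calibration.** The default (g=0.2, two ABP slow waves of 3 mmHg at
0.02 Hz and 2 mmHg at 0.033 Hz, intrinsic amplitude 2.5 cm/s, noise SD
2 cm/s) was chosen from the closed form to put the expected summary nMxa at
≈ 0.21–0.23, the healthy-adult mean reported for this index family
(0.21, SD 0.16). Measured cohort means over 50 seeds land at ≈ 0.21–0.24.

**What the generator does not emulate.** Two known departures from ideal
behaviour, both small and characterized by tests: (i) the cardiac pulse
train shared by ABP and FV leaves correlated partial-beat residuals in the
10-s block means, adding ≈ +0.03 to the correlation null at g=0; (ii) block
series of band-limited signals are strongly autocorrelated, so the spread of
a 30-block sample correlation under the null (SD ≈ 0.23) is wider than the
iid 1/√30 ≈ 0.18. Real recordings additionally contain nonstationary heart
rate, respiration, vasomotion with continuous spectra, and measurement
drift that the generator does not model — passing tests demonstrate the
pipeline's correctness and calibration under the stated model, not
performance on clinical data.

**THRT sessions.** Compressions are superimposed multiplicatively on one FV
channel at a time (unilateral protocol; sides ordered left, left, right,
right): ×(1−drop) during the compression, then ×(1+h) held for `hold_s`
(default 5 s) after release, decaying exponentially with `recovery_tau_s`
(default 10 s). The plateau guarantees the assessed post-release peaks 2–4
sit at exactly (1+h)·baseline, so the analytically expected THRR equals
1+h, while the decay completes well before the next episode's baseline
(residual < 10⁻³ at 60-s spacing). A pure exponential from release would
make the expected ratio depend on the heart rate/τ ratio and, for large τ,
contaminate the next baseline — the plateau-plus-decay envelope is the
simplest shape that makes the generator's ground truth exact. Per-episode
ratios still scatter by a few percent (slow waves and noise move the
baseline between the pre- and post-compression beats); session and
multi-seed means recover 1+h to well within 0.02.

## Problem sizes and numerical choices

- Study-protocol simulations use 40-min (2400 s) recordings at 125 Hz for
  the correlation index — 30 min of analysis plus headroom for artefacts, as
  in the clinical protocol — and 360-s sessions for the compression test.
  Generator-level statistical tests (closed form, monotonicity, null
  spread) use 300–1200 s recordings and block-level correlations, which are
  the same computation without the artefact-masking stage.
- Correlations use `numpy.corrcoef`; tests hold an independent pure-Python
  sum-formula oracle and a from-scratch moving-window recomputation
  (agreement to 1e-12 and 1e-9 respectively).
- The power projection uses the two-sample normal approximation
  n = 2σ²(z₁₋α/₂ + z₁₋β)²/Δ² with a +1 t-correction, rounded up; for the
  default scenario (Δ = 0.19, σ = 0.16, α = 0.05, power 0.90) this gives 16
  per group. The number of groups is an explicit input; tests cross-check
  against statsmodels' `TTestIndPower` within ±1.
- Block grids are anchored at the recording start; trailing partial blocks
  are dropped. Intervals are half-open `[start, end)`, times are seconds
  from recording start, 0-based. Waveform files store values with 17
  significant digits so read(write(x)) is bit-exact.
- The compression auto-detector references the median systolic value of the
  10 most recent beats *not already flagged as suppressed*; a plain rolling
  median would absorb the compression itself within ~5 beats and truncate
  detected episodes.

## Known limitations

- The sides-combination rule for a single per-participant nMxa (unweighted
  left/right mean) is a convention; side-specific values are always
  reported alongside.
- Auto-detected compression edges are quantized to beats (±½ beat), which
  is why the spacing and duration flags carry 1-s tolerances.
- The generator's artefact model (dropouts, spikes, baseline steps) is
  deliberately simple plumbing for exercising the masking stage; it is not
  a model of probe or cuff physics.
- PCSS scoring assumes the 21-item, 0–6-per-item schema (total /126); the
  scale's item semantics are out of scope.
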