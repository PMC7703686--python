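"""Synthetic hemodynamic signal generator with known autoregulation status.

Generates paired arterial-blood-pressure and bilateral cerebral-blood-flow-
velocity waveforms whose statistical structure matches what the nMxa and THRR
analyses assume: a pulsatile cardiac component riding on slow (0.005-0.05 Hz)
oscillations, with the flow channels coupled to the pressure slow waves by a
tunable pressure-passivity gain g.

Model
-----
ABP(t)   = abp_mean + S(t) + A_p * pulse(t)
FV_x(t)  = fv_mean + g * (fv_mean/abp_mean) * S(t)
           + (1-g) * I_x(t) + A_f * pulse(t) + noise_x(t)

where S(t) is the configured sum of slow sinusoids, I_x(t) is a per-side
intrinsic slow sinusoid (random frequency and phase within the slow band),
pulse(t) is a zero-mean asymmetric cardiac pulse template locked to a jittered
beat train shared by all channels, and noise_x is white Gaussian noise.

At g=1 with no intrinsic fluctuation or noise the flow slow component is an
exact affine image of the pressure slow component (fully pressure-passive,
expected moving-window correlation 1).  At g=0 flow and pressure slow waves
are independent (expected correlation 0).  The expected block-level Pearson
correlation admits the closed form

    r = g*sa / sqrt(g^2*sa^2 + (1-g)^2*si^2 + sn^2)

with sa the scaled ABP slow-wave SD, si the intrinsic SD and sn the residual
noise SD after block averaging; tests verify the generator against it.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .config import ArtefactSpec, SimulationConfig, ThrtSimSpec, substream
from .errors import ValidationError
from .recording import WaveformRecording

# --- cardiac pulse template -------------------------------------------------
# gamma-like shape: fast systolic upstroke peaking 20% into the beat, slow
# diastolic decay; p(0)=0 and p(1)~8e-3 so consecutive beats join smoothly.
_PEAK_PHASE = 0.2


def pulse_template(phase: np.ndarray) -> np.ndarray:
    """Normalised pulse shape on beat phase in [0, 1), max value 1 at phase 0.2."""
    u = np.asarray(phase, dtype=np.float64) / _PEAK_PHASE
    return u * u * np.exp(2.0 * (1.0 - u))


def _template_mean() -> float:
    # continuous mean of the template over one beat (analytic via the
    # incomplete-gamma antiderivative would do; a fine grid is simpler and
    # accurate to ~1e-12 for this smooth shape)
    phi = np.linspace(0.0, 1.0, 200_001)
    return float(np.trapezoid(pulse_template(phi), phi))


#: mean of the pulse template over a beat; subtracted so each beat is zero-mean
TEMPLATE_MEAN = _template_mean()


def systolic_offset(pulse_amp: float) -> float:
    """Offset of the systolic peak above the channel mean for a pulse amplitude."""
    return pulse_amp * (1.0 - TEMPLATE_MEAN)


def diastolic_offset(pulse_amp: float) -> float:
    """Offset of the diastolic trough below the channel mean (negative)."""
    return -pulse_amp * TEMPLATE_MEAN


def _beat_train(config: SimulationConfig, n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """Jittered beat onset times and intervals covering the recording."""
    rng = config.rng("hr")
    base = 60.0 / config.hr_bpm
    n_beats = int(np.ceil(config.duration_s / base * 1.25)) + 8
    intervals = base * (1.0 + config.hr_jitter * rng.standard_normal(n_beats))
    intervals = np.clip(intervals, 0.3, 2.0)
    onsets = np.concatenate([[0.0], np.cumsum(intervals)])[:-1]
    return onsets, intervals


def _pulse_wave(t: np.ndarray, onsets: np.ndarray, intervals: np.ndarray,
                amp: float) -> np.ndarray:
    """Zero-mean cardiac pulsatility sampled at times t."""
    idx = np.searchsorted(onsets, t, side="right") - 1
    idx = np.clip(idx, 0, len(intervals) - 1)
    phase = (t - onsets[idx]) / intervals[idx]
    return amp * (pulse_template(np.clip(phase, 0.0, 1.0)) - TEMPLATE_MEAN)


def _slow_component(t: np.ndarray, config: SimulationConfig) -> np.ndarray:
    s = np.zeros_like(t)
    for f, a, ph in config.slow_waves:
        s += a * np.sin(2.0 * np.pi * f * t + ph)
    return s


def _intrinsic_wave(t: np.ndarray, amp: float, rng: np.random.Generator) -> np.ndarray:
    """Per-side slow fluctuation independent of ABP: one seeded sinusoid with
    random frequency inside the slow band and random phase (SD = amp/sqrt(2))."""
    f = rng.uniform(0.008, 0.045)
    ph = rng.uniform(0.0, 2.0 * np.pi)
    return amp * np.sin(2.0 * np.pi * f * t + ph)


def synth_recording(config: SimulationConfig) -> WaveformRecording:
    """Generate a three-channel (abp, fvl, fvr) recording from the config.

    The true coupling gain and config digest are stored in ``meta`` so that
    downstream estimates can be compared against ground truth.  Identical
    configs (including seed) produce bit-identical output.
    """
    config.validate()
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs

    onsets, intervals = _beat_train(config, n)
    slow = _slow_component(t, config)
    abp = config.abp_mean + slow + _pulse_wave(t, onsets, intervals, config.abp_pulse_amp)
    if config.resp_wave is not None:
        f_resp, a_resp = config.resp_wave
        abp = abp + a_resp * np.sin(2.0 * np.pi * f_resp * t)

    g = config.coupling_gain
    scale = config.fv_mean / config.abp_mean
    fv_pulse = _pulse_wave(t, onsets, intervals, config.fv_pulse_amp)

    channels = {"abp": abp}
    for side in ("fvl", "fvr"):
        rng = config.rng(side)
        intrinsic = _intrinsic_wave(t, config.intrinsic_slow_amp, rng)
        noise = config.noise_sd * rng.standard_normal(n) if config.noise_sd > 0 else 0.0
        channels[side] = (
            config.fv_mean
            + g * scale * slow
            + (1.0 - g) * intrinsic
            + fv_pulse
            + noise
        )

    meta = {
        "source": "synth",
        "coupling_gain": g,
        "seed": config.seed,
        "config_digest": config.digest(),
        "beat_onsets_s": onsets,
        "fs": config.fs,
    }
    return WaveformRecording(channels=channels, fs=config.fs, meta=meta)


# --- THRT session -----------------------------------------------------------

def thrt_side_sequence(n_compressions: int) -> list[str]:
    """Side assignment for a compression series: pairs left then right."""
    sides = []
    for i in range(n_compressions):
        sides.append("left" if (i // 2) % 2 == 0 else "right")
    return sides


def synth_thrt_session(
    config: SimulationConfig, spec: ThrtSimSpec
) -> tuple[WaveformRecording, list[dict]]:
    """Simulate a transient-hyperaemic-response-test session.

    Each compression multiplies the ipsilateral flow-velocity channel by
    (1 - drop_frac) for its duration; on release the channel is scaled by
    (1 + overshoot_frac) for ``hold_s`` seconds and then relaxes to baseline
    exponentially.  The contralateral channel is untouched (unilateral
    protocol).  Returns the recording and the ground-truth compression
    intervals as ``[{"side", "start_s", "end_s"}, ...]`` (half-open).
    """
    config.validate()
    spec.validate()
    if config.duration_s < spec.total_span_s():
        raise ValidationError(
            f"duration_s={config.duration_s} cannot accommodate "
            f"{spec.n_compressions} compressions spaced {spec.spacing_s}s "
            f"(needs >= {spec.total_span_s():.0f}s)"
        )
    rec = synth_recording(config)
    n = rec.n_samples
    fs = rec.fs
    t = rec.times

    sides = thrt_side_sequence(spec.n_compressions)
    truth: list[dict] = []
    env = {"left": np.ones(n), "right": np.ones(n)}
    h = spec.overshoot_frac
    for k, side in enumerate(sides):
        t0 = spec.lead_in_s + k * (spec.compression_len_s + spec.spacing_s)
        t1 = t0 + spec.compression_len_s
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        e = env[side]
        e[i0:i1] = 1.0 - spec.drop_frac
        i_hold = min(int(round((t1 + spec.hold_s) * fs)), n)
        e[i1:i_hold] = 1.0 + h
        if i_hold < n:
            if spec.recovery_tau_s > 0:
                tail = t[i_hold:] - t[i_hold] if i_hold < n else np.array([])
                e[i_hold:] = 1.0 + h * np.exp(-tail / spec.recovery_tau_s)
            else:
                e[i_hold:] = 1.0
        truth.append({"side": side, "start_s": t0, "end_s": t1})

    channel_of = {"left": "fvl", "right": "fvr"}
    for side, ch in channel_of.items():
        rec.channels[ch] = rec.channels[ch] * env[side]
    rec.meta["thrt_truth"] = truth
    rec.meta["thrt_spec"] = spec
    return rec, truth


def expected_thrr(spec: ThrtSimSpec, hr_bpm: float = 70.0) -> float:
    """Analytic session ratio for the generator's overshoot envelope.

    Post-release systolic peaks fall approximately at (k - 1 + peak_phase)
    beat intervals after release; the ratio averages the envelope at peaks
    2-4 (the first peak is ignored by the clinical definition).
    """
    beat = 60.0 / hr_bpm
    total = 0.0
    for k in (2, 3, 4):
        tk = (k - 1 + _PEAK_PHASE) * beat
        if tk <= spec.hold_s:
            f = 1.0 + spec.overshoot_frac
        elif spec.recovery_tau_s > 0:
            f = 1.0 + spec.overshoot_frac * np.exp(-(tk - spec.hold_s) / spec.recovery_tau_s)
        else:
            f = 1.0
        total += f
    return total / 3.0


# --- artefact injection -----------------------------------------------------

def inject_artefacts(
    rec: WaveformRecording,
    spec: ArtefactSpec,
    seed: Optional[int] = None,
) -> tuple[WaveformRecording, dict[str, np.ndarray]]:
    """Corrupt a copy of the recording; return it with the truth mask.

    Dropouts zero the signal for ``dropout_len_s``; spikes add an excursion of
    ``spike_amp`` channel-SDs at single samples; a baseline shift (probability
    ``shift_prob``) adds a step of ``shift_frac``×channel-mean from a random
    point onward.  The boolean truth mask per channel covers exactly the
    corrupted samples; all other samples are bit-identical to the input.
    """
    spec.validate()
    if seed is None:
        seed = int(rec.meta.get("seed", 0))
    rng = substream(seed, "artefacts")
    out = rec.copy()
    n = out.n_samples
    fs = out.fs
    minutes = out.duration_s / 60.0
    truth: dict[str, np.ndarray] = {}

    for name in sorted(out.channels):
        x = out.channels[name]
        mask = np.zeros(n, dtype=bool)

        n_drop = rng.poisson(spec.dropout_rate * minutes)
        drop_len = max(1, int(round(spec.dropout_len_s * fs)))
        for _ in range(n_drop):
            start = int(rng.integers(0, max(1, n - drop_len)))
            x[start : start + drop_len] = 0.0
            mask[start : start + drop_len] = True

        n_spike = rng.poisson(spec.spike_rate * minutes)
        if n_spike > 0:
            sd = float(np.std(rec.channels[name]))
            pos = rng.integers(0, n, size=n_spike)
            sign = rng.choice([-1.0, 1.0], size=n_spike)
            x[pos] = x[pos] + sign * spec.spike_amp * sd
            mask[pos] = True

        if spec.shift_prob > 0 and rng.random() < spec.shift_prob:
            start = int(rng.integers(n // 4, 3 * n // 4))
            x[start:] = x[start:] + spec.shift_frac * float(np.mean(rec.channels[name]))
            mask[start:] = True

        truth[name] = mask
    out.meta["artefact_truth"] = truth
    return out, truth
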