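"""Simulator configuration dataclasses and seeded substream handling.

The generator is parameterised by a single :class:`SimulationConfig`.  One
global seed is expanded into named substreams ("abp", "fvl", "fvr",
"artefacts", "thrt", ...) so that toggling one stochastic component (e.g.
artefact injection) does not perturb the draws of another.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

SLOW_BAND = (0.005, 0.05)  # Hz, the spontaneous slow-wave band probed for CA

# fixed substream keys so that streams are stable across code changes
_STREAMS = {"abp": 1, "fvl": 2, "fvr": 3, "artefacts": 4, "thrt": 5, "hr": 6}


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the named, reproducible random substream for a global seed."""
    if name not in _STREAMS:
        raise ValidationError(f"unknown substream {name!r}")
    ss = np.random.SeedSequence(int(seed), spawn_key=(_STREAMS[name],))
    return np.random.default_rng(ss)


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value}")
    return value


@dataclass
class ArtefactSpec:
    """Rates and shapes of injected recording artefacts.

    ``dropout_rate``/``spike_rate`` are events per minute; ``dropout_len_s``
    is the length of each signal-loss run; ``spike_amp`` is the spike height
    in multiples of the channel standard deviation; ``shift_prob`` is the
    probability of a single baseline step-change per recording.
    """

    dropout_rate: float = 0.0
    dropout_len_s: float = 2.0
    spike_rate: float = 0.0
    spike_amp: float = 10.0
    shift_prob: float = 0.0
    shift_frac: float = 0.1

    def validate(self) -> "ArtefactSpec":
        for name in ("dropout_rate", "spike_rate"):
            v = _check_finite(name, getattr(self, name))
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        if _check_finite("dropout_len_s", self.dropout_len_s) <= 0:
            raise ValidationError("dropout_len_s must be > 0")
        p = _check_finite("shift_prob", self.shift_prob)
        if not 0 <= p <= 1:
            raise ValidationError(f"shift_prob must be in [0,1], got {p}")
        return self


@dataclass
class SimulationConfig:
    """Full parameterisation of the synthetic hemodynamic generator.

    The coupling gain ``g`` in [0, 1] sets the autoregulation status of the
    simulated subject: g=1 means cerebral flow velocity is fully pressure-
    passive (its slow waves are an affine image of the ABP slow waves, the
    impaired-autoregulation limit) while g=0 decouples flow from pressure
    entirely (ideal autoregulation).  The default parameterisation is the
    intact-autoregulation calibration discussed in docs/methods.md.
    """

    duration_s: float = 2400.0
    fs: float = 125.0
    hr_bpm: float = 70.0
    hr_jitter: float = 0.03
    abp_mean: float = 90.0
    abp_pulse_amp: float = 40.0
    #: (frequency Hz, amplitude mmHg, phase rad) within the slow-wave band
    slow_waves: Sequence[tuple[float, float, float]] = (
        (0.02, 3.0, 0.0),
        (0.033, 2.0, 1.0),
    )
    resp_wave: Optional[tuple[float, float]] = None
    fv_mean: float = 55.0
    fv_pulse_amp: float = 30.0
    coupling_gain: float = 0.2
    intrinsic_slow_amp: float = 2.5
    noise_sd: float = 2.0
    artefact_spec: ArtefactSpec = field(default_factory=ArtefactSpec)
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if _check_finite("duration_s", self.duration_s) <= 0:
            raise ValidationError(f"duration_s must be > 0, got {self.duration_s}")
        if _check_finite("fs", self.fs) <= 0:
            raise ValidationError(f"fs must be > 0, got {self.fs}")
        if not 10 <= _check_finite("hr_bpm", self.hr_bpm) <= 300:
            raise ValidationError(f"hr_bpm out of plausible range: {self.hr_bpm}")
        if _check_finite("hr_jitter", self.hr_jitter) < 0:
            raise ValidationError("hr_jitter must be >= 0")
        g = _check_finite("coupling_gain", self.coupling_gain)
        if not 0.0 <= g <= 1.0:
            raise ValidationError(f"coupling_gain must be in [0,1], got {g}")
        for f, a, _ in self.slow_waves:
            if not SLOW_BAND[0] <= f <= SLOW_BAND[1]:
                raise ValidationError(
                    f"slow-wave frequency {f} Hz outside the "
                    f"{SLOW_BAND[0]}-{SLOW_BAND[1]} Hz band"
                )
            if _check_finite("slow_wave amplitude", a) < 0:
                raise ValidationError("slow-wave amplitude must be >= 0")
        for name in ("abp_mean", "abp_pulse_amp", "fv_mean", "fv_pulse_amp"):
            if _check_finite(name, getattr(self, name)) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if _check_finite("intrinsic_slow_amp", self.intrinsic_slow_amp) < 0:
            raise ValidationError("intrinsic_slow_amp must be >= 0")
        if _check_finite("noise_sd", self.noise_sd) < 0:
            raise ValidationError("noise_sd must be >= 0")
        self.artefact_spec.validate()
        return self

    def rng(self, name: str) -> np.random.Generator:
        return substream(self.seed, name)

    def digest(self) -> str:
        """Stable hash of the full configuration, for provenance metadata."""
        payload = asdict(self)
        payload["slow_waves"] = [list(w) for w in self.slow_waves]
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ThrtSimSpec:
    """Parameters of a simulated transient-hyperaemic-response-test session.

    The clinical protocol performs two left and two right carotid
    compressions of 5-7 s, spaced at least one minute apart to let the
    autoregulatory system recover.  ``drop_frac`` is the fractional systolic
    flow-velocity reduction during compression (the test requires >30%);
    ``overshoot_frac`` is the post-release hyperaemic excess over baseline.
    The overshoot is held at its full value for ``hold_s`` seconds after
    release (covering the assessed systolic peaks) and then decays
    exponentially with time constant ``recovery_tau_s``, so the analytically
    expected ratio for a session equals 1 + overshoot_frac.
    """

    n_compressions: int = 4
    compression_len_s: float = 6.0
    spacing_s: float = 60.0
    drop_frac: float = 0.35
    overshoot_frac: float = 0.15
    hold_s: float = 5.0
    recovery_tau_s: float = 10.0
    lead_in_s: float = 60.0

    def validate(self) -> "ThrtSimSpec":
        if self.n_compressions < 1:
            raise ValidationError("n_compressions must be >= 1")
        if not 0 < _check_finite("drop_frac", self.drop_frac) < 1:
            raise ValidationError(f"drop_frac must be in (0,1), got {self.drop_frac}")
        if _check_finite("spacing_s", self.spacing_s) < 60:
            raise ValidationError(
                f"spacing_s must be >= 60 s (protocol spaces tests 1 min apart), "
                f"got {self.spacing_s}"
            )
        if _check_finite("overshoot_frac", self.overshoot_frac) < 0:
            raise ValidationError("overshoot_frac must be >= 0")
        if _check_finite("compression_len_s", self.compression_len_s) <= 0:
            raise ValidationError("compression_len_s must be > 0")
        if _check_finite("recovery_tau_s", self.recovery_tau_s) < 0:
            raise ValidationError("recovery_tau_s must be >= 0")
        if _check_finite("hold_s", self.hold_s) < 0:
            raise ValidationError("hold_s must be >= 0")
        return self

    def total_span_s(self) -> float:
        """Time from session start to end of the last recovery gap."""
        per = self.compression_len_s + self.spacing_s
        return self.lead_in_s + self.n_compressions * per
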