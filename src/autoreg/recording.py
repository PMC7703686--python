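"""In-memory containers for waveforms, beats and block averages.

A :class:`WaveformRecording` holds uniformly sampled channels (arterial blood
pressure in mm Hg, left/right middle-cerebral-artery flow velocity in cm/s)
with one boolean artefact mask per channel.  :class:`BeatSeries` and
:class:`BlockSeries` are the two derived representations the autoregulation
indices consume: per-beat systolic/diastolic/mean values for the hyperaemic
response test, and 10-s block means (the slow-wave surrogate) for nMxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

#: canonical channel names and units
CHANNEL_UNITS = {"abp": "mmHg", "fvl": "cm/s", "fvr": "cm/s"}

FV_CHANNELS = ("fvl", "fvr")


@dataclass
class WaveformRecording:
    """Multichannel uniformly sampled waveform recording.

    Parameters
    ----------
    channels
        Mapping of channel name ("abp", "fvl", "fvr") to 1-D float64 arrays.
        All channels must have equal length.
    fs
        Sampling rate in Hz (the study protocol records at 125 Hz).
    start_s
        Time offset of the first sample, seconds.
    masks
        Optional boolean artefact mask per channel (True = corrupted sample).
        Missing masks are initialised to all-False.
    meta
        Free-form provenance metadata (source file, simulation parameters).
    """

    channels: dict[str, np.ndarray]
    fs: float
    start_s: float = 0.0
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0 or not np.isfinite(self.fs):
            raise ValidationError(f"fs must be positive and finite, got {self.fs}")
        if not self.channels:
            raise ValidationError("recording must contain at least one channel")
        lengths = {name: len(arr) for name, arr in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise ValidationError(f"channel lengths differ: {lengths}")
        n = self.n_samples
        for name in self.channels:
            self.channels[name] = np.asarray(self.channels[name], dtype=np.float64)
            if name not in self.masks:
                self.masks[name] = np.zeros(n, dtype=bool)
            else:
                self.masks[name] = np.asarray(self.masks[name], dtype=bool)
                if len(self.masks[name]) != n:
                    raise ValidationError(
                        f"mask length for {name!r} ({len(self.masks[name])}) "
                        f"!= channel length ({n})"
                    )

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from recording start (0-based)."""
        return self.start_s + np.arange(self.n_samples) / self.fs

    def fv_channels(self) -> list[str]:
        return [c for c in FV_CHANNELS if c in self.channels]

    def copy(self) -> "WaveformRecording":
        return WaveformRecording(
            channels={k: v.copy() for k, v in self.channels.items()},
            fs=self.fs,
            start_s=self.start_s,
            masks={k: v.copy() for k, v in self.masks.items()},
            meta=dict(self.meta),
        )

    def merge_mask(self, extra: Mapping[str, np.ndarray]) -> None:
        """OR the given per-channel masks into the recording masks."""
        for name, m in extra.items():
            if name in self.masks:
                self.masks[name] |= np.asarray(m, dtype=bool)


@dataclass
class BeatSeries:
    """Per-beat metrics extracted from one pulsatile channel.

    ``onset_s`` are systolic-peak times in seconds (strictly increasing);
    ``systolic``/``diastolic``/``mean`` are per-beat values in channel units;
    ``valid`` flags beats free of masked samples and with a physiological
    inter-beat interval (0.3–2.0 s).
    """

    onset_s: np.ndarray
    systolic: np.ndarray
    diastolic: np.ndarray
    mean: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.onset_s = np.asarray(self.onset_s, dtype=np.float64)
        for name in ("systolic", "diastolic", "mean"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.onset_s)
        for name in ("systolic", "diastolic", "mean", "valid"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"BeatSeries field {name!r} length mismatch")
        if n > 1 and not np.all(np.diff(self.onset_s) > 0):
            raise ValidationError("beat onset times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onset_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": self.onset_s,
                "systolic": self.systolic,
                "diastolic": self.diastolic,
                "mean": self.mean,
                "valid": self.valid,
            }
        )


@dataclass
class BlockSeries:
    """Non-overlapping block means of one channel (slow-wave surrogate).

    Averaging over 10-s blocks suppresses cardiac and respiratory frequency
    content while retaining the 0.005–0.05 Hz slow waves that the moving
    correlation index operates on.
    """

    start_s: np.ndarray
    value: np.ndarray
    valid_frac: np.ndarray
    valid: np.ndarray
    block_len_s: float = 10.0

    def __post_init__(self) -> None:
        self.start_s = np.asarray(self.start_s, dtype=np.float64)
        self.value = np.asarray(self.value, dtype=np.float64)
        self.valid_frac = np.asarray(self.valid_frac, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.start_s)
        for name in ("value", "valid_frac", "valid"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"BlockSeries field {name!r} length mismatch")
        if self.block_len_s <= 0:
            raise ValidationError("block_len_s must be positive")

    def __len__(self) -> int:
        return len(self.start_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_s": self.start_s,
                "value": self.value,
                "valid_frac": self.valid_frac,
                "valid": self.valid,
            }
        )
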