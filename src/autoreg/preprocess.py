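"""Raw-waveform preprocessing: artefact masking, beat detection, block means.

The analysis chain is: mask physiologically implausible or corrupted samples,
extract per-beat systolic/diastolic/mean values (for the hyperaemic response
test), and reduce each channel to 10-s block averages (the slow-wave surrogate
consumed by the moving-correlation index).  No interpolation is performed
across masked gaps: invalid beats and blocks are simply excluded downstream,
mirroring how artefact removal leaves missing chunks in monitored data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy import ndimage, signal

from .errors import ValidationError
from .recording import BeatSeries, BlockSeries, WaveformRecording

logger = logging.getLogger(__name__)

#: physiological range limits per channel family (inclusive bounds; FV lower
#: bound exclusive: zero flow velocity is a lost-signal reading)
DEFAULT_LIMITS: dict[str, tuple[float, float]] = {
    "abp": (20.0, 300.0),
    "fvl": (0.0, 150.0),
    "fvr": (0.0, 150.0),
}

FLATLINE_MIN_S = 2.0
SPIKE_ROBUST_SDS = 5.0
REFRACTORY_S = 0.3
PROMINENCE_FRAC = 0.25


def _flatline_mask(x: np.ndarray, fs: float) -> np.ndarray:
    """Mark runs of >= FLATLINE_MIN_S seconds with zero sample-to-sample change."""
    n = len(x)
    mask = np.zeros(n, dtype=bool)
    if n < 2:
        return mask
    flat = np.diff(x) == 0.0
    min_run = max(2, int(round(FLATLINE_MIN_S * fs)) - 1)
    # run-length encode the boolean diff sequence
    edges = np.flatnonzero(np.diff(flat.astype(np.int8)))
    starts = np.concatenate([[0], edges + 1])
    ends = np.concatenate([edges + 1, [len(flat)]])
    for s, e in zip(starts, ends):
        if flat[s] and (e - s) >= min_run:
            mask[s : e + 1] = True
    return mask


def _spike_mask(x: np.ndarray, fs: float) -> np.ndarray:
    """Isolated excursions > SPIKE_ROBUST_SDS robust SDs from a 1-s rolling median."""
    size = max(3, int(round(fs)) | 1)  # odd kernel
    med = ndimage.median_filter(x, size=size, mode="nearest")
    resid = x - med
    mad = np.median(np.abs(resid - np.median(resid)))
    robust_sd = 1.4826 * mad
    if robust_sd <= 0:
        return np.zeros(len(x), dtype=bool)
    return np.abs(resid) > SPIKE_ROBUST_SDS * robust_sd


def detect_artefacts(
    rec: WaveformRecording,
    limits: Optional[Mapping[str, tuple[float, float]]] = None,
) -> dict[str, np.ndarray]:
    """Per-channel artefact masks: range violations, flatlines, spikes.

    Samples outside the physiological limits (ABP outside [20, 300] mmHg, FV
    outside (0, 150] cm/s), flatline runs of at least 2 s, and isolated
    spikes more than 5 robust SDs from a 1-s rolling median are marked.  The
    returned mask is the union with any pre-existing mask on the recording
    (masks only ever grow).
    """
    if rec.n_samples == 0:
        raise ValidationError("cannot detect artefacts on an empty recording")
    limits = dict(DEFAULT_LIMITS) | dict(limits or {})
    out: dict[str, np.ndarray] = {}
    for name, x in rec.channels.items():
        mask = rec.masks[name].copy()
        lo, hi = limits.get(name, (-np.inf, np.inf))
        if name.startswith("fv"):
            mask |= (x <= lo) | (x > hi)  # zero flow = lost signal
        else:
            mask |= (x < lo) | (x > hi)
        mask |= ~np.isfinite(x)
        mask |= _flatline_mask(x, rec.fs)
        mask |= _spike_mask(x, rec.fs)
        out[name] = mask
    return out


def _rolling_amplitude(x: np.ndarray, mask: np.ndarray, fs: float,
                       seg_s: float = 10.0) -> np.ndarray:
    """Per-sample pulse-amplitude estimate: p95-p5 over 10-s segments."""
    n = len(x)
    seg = max(1, int(round(seg_s * fs)))
    n_seg = max(1, int(np.ceil(n / seg)))
    centers = np.empty(n_seg)
    amps = np.empty(n_seg)
    last = np.nan
    for i in range(n_seg):
        sl = slice(i * seg, min((i + 1) * seg, n))
        xs = x[sl][~mask[sl]]
        centers[i] = (sl.start + min(sl.stop, n)) / 2.0
        if len(xs) >= 10:
            last = float(np.percentile(xs, 95) - np.percentile(xs, 5))
        amps[i] = last
    # back-fill leading NaNs, then linear interpolation between centers
    if np.all(np.isnan(amps)):
        return np.full(n, np.nan)
    valid = ~np.isnan(amps)
    amps[~valid] = amps[valid][0]
    return np.interp(np.arange(n), centers, amps)


def detect_beats(
    channel: np.ndarray,
    fs: float,
    mask: Optional[np.ndarray] = None,
) -> BeatSeries:
    """Locate systolic peaks and per-beat metrics in one pulsatile channel.

    Peaks are local maxima with prominence at least 25% of the local pulse
    amplitude, separated by a 0.3-s refractory period.  The beat interval
    runs from one systolic peak to the next; the diastolic value is the
    minimum and the per-beat mean the average over that interval.  Beats
    overlapping masked samples, or with an interval outside 0.3-2.0 s, are
    flagged invalid.
    """
    x = np.asarray(channel, dtype=np.float64)
    n = len(x)
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        logger.warning("detect_beats: channel fully masked, returning empty series")
        return BeatSeries(
            onset_s=np.empty(0), systolic=np.empty(0), diastolic=np.empty(0),
            mean=np.empty(0), valid=np.empty(0, dtype=bool),
        )
    if (~mask).sum() / fs < 10.0:
        raise ValidationError("detect_beats requires >= 10 s of unmasked signal")

    amp = _rolling_amplitude(x, mask, fs)
    global_floor = PROMINENCE_FRAC * np.nanmin(amp)
    peaks, props = signal.find_peaks(
        np.where(mask, np.nanmedian(x[~mask]), x),
        distance=max(1, int(round(REFRACTORY_S * fs))),
        prominence=max(global_floor * 0.2, 1e-12),
    )
    keep = props["prominences"] >= PROMINENCE_FRAC * amp[peaks]
    peaks = peaks[keep]
    if len(peaks) == 0:
        logger.warning("detect_beats: no systolic peaks found")
        return BeatSeries(
            onset_s=np.empty(0), systolic=np.empty(0), diastolic=np.empty(0),
            mean=np.empty(0), valid=np.empty(0, dtype=bool),
        )

    n_beats = len(peaks)
    onset_s = peaks / fs
    systolic = x[peaks]
    diastolic = np.full(n_beats, np.nan)
    mean = np.full(n_beats, np.nan)
    valid = np.ones(n_beats, dtype=bool)
    bounds = np.append(peaks, n)
    median_iv = float(np.median(np.diff(peaks))) / fs if n_beats > 1 else 1.0
    for i in range(n_beats):
        a, b = bounds[i], bounds[i + 1]
        if i == n_beats - 1:
            b = min(n, a + int(round(median_iv * fs)))
        seg = x[a:b]
        if len(seg) >= 2:
            diastolic[i] = seg.min()
            mean[i] = seg.mean()
        else:
            valid[i] = False
        iv = (b - a) / fs
        if not (0.3 <= iv <= 2.0):
            valid[i] = False
        if mask[a:b].any():
            valid[i] = False
    return BeatSeries(onset_s=onset_s, systolic=systolic, diastolic=diastolic,
                      mean=mean, valid=valid)


def block_average(
    channel: np.ndarray,
    mask: Optional[np.ndarray],
    fs: float,
    block_len_s: float = 10.0,
    min_valid_frac: float = 0.5,
) -> BlockSeries:
    """Non-overlapping block means over unmasked samples only.

    The block grid is anchored at the recording start; a trailing partial
    block is dropped.  A block whose valid-sample fraction falls below
    ``min_valid_frac`` is marked invalid (its mean is still reported when any
    valid samples exist).
    """
    if block_len_s <= 0:
        raise ValidationError(f"block_len_s must be > 0, got {block_len_s}")
    if fs * block_len_s < 1:
        raise ValidationError("block must contain at least one sample")
    x = np.asarray(channel, dtype=np.float64)
    n = len(x)
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    blk = int(round(fs * block_len_s))
    n_blocks = n // blk
    starts = np.arange(n_blocks) * block_len_s
    values = np.full(n_blocks, np.nan)
    fracs = np.zeros(n_blocks)
    if n_blocks:
        xm = np.where(mask, np.nan, x)[: n_blocks * blk].reshape(n_blocks, blk)
        counts = np.sum(~np.isnan(xm), axis=1)
        fracs = counts / blk
        with np.errstate(invalid="ignore"):
            sums = np.nansum(xm, axis=1)
            values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    valid = (fracs >= min_valid_frac) & np.isfinite(values)
    return BlockSeries(start_s=starts, value=values, valid_frac=fracs,
                       valid=valid, block_len_s=block_len_s)


@dataclass
class PreprocessResult:
    """Recording with artefact masks applied plus derived block series."""

    recording: WaveformRecording
    blocks: dict[str, BlockSeries]


def preprocess_recording(
    rec: WaveformRecording,
    block_len_s: float = 10.0,
    min_valid_frac: float = 0.5,
    limits: Optional[Mapping[str, tuple[float, float]]] = None,
) -> PreprocessResult:
    """Run artefact detection and block averaging on every channel."""
    masked = rec.copy()
    masks = detect_artefacts(masked, limits=limits)
    masked.merge_mask(masks)
    blocks = {
        name: block_average(masked.channels[name], masked.masks[name], masked.fs,
                            block_len_s=block_len_s, min_valid_frac=min_valid_frac)
        for name in masked.channels
    }
    return PreprocessResult(recording=masked, blocks=blocks)
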