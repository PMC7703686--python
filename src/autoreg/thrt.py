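"""Transient hyperaemic response test: episode segmentation and the THRR.

A THRT session consists of brief (5-7 s) unilateral carotid compressions,
spaced at least one minute apart, during which ipsilateral middle-cerebral-
artery systolic flow velocity must fall by more than 30%.  On release, intact
autoregulation produces a transient hyperaemic overshoot: the first
post-release systolic peak is ignored and the mean of the next three is
compared with the resting (pre-compression) systolic velocity.  A ratio of at
least 1.10 (a >9% flow increase) indicates preserved autoregulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .recording import BeatSeries

logger = logging.getLogger(__name__)

#: THRR at or above this value indicates preserved autoregulation (inclusive)
PRESERVED_THRESHOLD = 1.10
#: required fractional systolic drop during compression
DROP_THRESHOLD = 0.30
#: compressions should last 5-7 s; flag computed with +/- 1 s tolerance
DURATION_RANGE_S = (5.0, 7.0)
DURATION_TOL_S = 1.0
#: protocol spacing between tests, with 1 s tolerance for detected edges
SPACING_MIN_S = 60.0
SPACING_TOL_S = 1.0
#: auto-detection accepts runs of suppressed systolic beats lasting 3-10 s
AUTO_DURATION_S = (3.0, 10.0)

FLAG_NAMES = ("drop_ok", "duration_ok", "spacing_ok", "signal_ok")


@dataclass
class ThrtEpisode:
    """One segmented carotid-compression episode with validity flags."""

    side: str  # "left" | "right"
    start_s: float
    end_s: float
    baseline_systolic: np.ndarray  # per-beat systolic FV preceding compression
    nadir_systolic: float
    post_peaks: np.ndarray  # ordered post-release per-beat systolic FV
    flags: dict[str, bool]
    source: str = "auto_detected"  # or "manual_annotation"
    exclusion_reason: Optional[str] = None

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def all_flags_ok(self) -> bool:
        return all(self.flags.get(k, False) for k in FLAG_NAMES)

    def failed_flags(self) -> list[str]:
        return [k for k in FLAG_NAMES if not self.flags.get(k, False)]


@dataclass
class SideThrr:
    thrr: Optional[float]
    n_valid: int
    n_total: int
    classification: str  # "preserved" | "impaired" | "not_obtainable"


@dataclass
class ThrrResult:
    """Per-side session THRR with an episode-level audit trail."""

    sides: dict[str, SideThrr]
    episodes: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sides": {
                s: {
                    "thrr": v.thrr,
                    "n_valid": v.n_valid,
                    "n_total": v.n_total,
                    "classification": v.classification,
                }
                for s, v in sorted(self.sides.items())
            },
            "episodes": self.episodes,
        }


def classify(thrr: Optional[float]) -> str:
    if thrr is None:
        return "not_obtainable"
    return "preserved" if thrr >= PRESERVED_THRESHOLD else "impaired"


def _episode_flags(
    ep_start: float,
    ep_end: float,
    baseline: np.ndarray,
    baseline_valid: np.ndarray,
    nadir: float,
    post_valid: np.ndarray,
    prev_end: Optional[float],
    baseline_n: int,
    post_n: int,
) -> dict[str, bool]:
    dur = ep_end - ep_start
    lo, hi = DURATION_RANGE_S
    flags = {
        "duration_ok": (lo - DURATION_TOL_S) <= dur <= (hi + DURATION_TOL_S),
        "spacing_ok": prev_end is None
        or (ep_start - prev_end) >= (SPACING_MIN_S - SPACING_TOL_S),
    }
    if len(baseline) >= 1 and np.mean(baseline) > 0 and np.isfinite(nadir):
        flags["drop_ok"] = nadir <= (1.0 - DROP_THRESHOLD) * float(np.mean(baseline))
    else:
        flags["drop_ok"] = False
    flags["signal_ok"] = (
        len(baseline) >= baseline_n
        and bool(np.all(baseline_valid))
        and len(post_valid) >= post_n
        and bool(np.all(post_valid[:post_n]))
    )
    return flags


def _build_episode(
    beats: BeatSeries,
    side: str,
    start_s: float,
    end_s: float,
    prev_end: Optional[float],
    source: str,
    baseline_n: int = 5,
    post_n: int = 4,
) -> ThrtEpisode:
    pre = np.flatnonzero(beats.onset_s < start_s)
    pre = pre[beats.valid[pre]][-baseline_n:]
    baseline = beats.systolic[pre]
    during = np.flatnonzero((beats.onset_s >= start_s) & (beats.onset_s < end_s))
    nadir = float(np.min(beats.systolic[during])) if len(during) else np.nan
    post = np.flatnonzero(beats.onset_s >= end_s)[: post_n]
    flags = _episode_flags(
        start_s, end_s, baseline, beats.valid[pre], nadir,
        beats.valid[post], prev_end, baseline_n, post_n,
    )
    return ThrtEpisode(
        side=side,
        start_s=float(start_s),
        end_s=float(end_s),
        baseline_systolic=baseline,
        nadir_systolic=nadir,
        post_peaks=beats.systolic[post],
        flags=flags,
        source=source,
    )


def find_compressions(
    fv_beats: BeatSeries,
    annotations: Optional[Sequence[tuple[float, float]]] = None,
    side: str = "left",
    baseline_n: int = 5,
    post_n: int = 4,
) -> list[ThrtEpisode]:
    """Segment compression episodes from a beat series.

    If ``annotations`` (list of half-open (start_s, end_s) intervals, as
    marked by the operator) is given, episodes are built around those marks.
    Otherwise episodes are auto-detected as maximal runs of beats whose
    systolic value stays at or below 70% of the median of the preceding 10
    beats, lasting 3-10 s; overlapping runs are merged.  Episodes starting
    less than ~60 s after the previous episode's end are flagged
    ``spacing_ok=False``.
    """
    if len(fv_beats) == 0:
        logger.warning("find_compressions: empty beat series")
        return []
    if annotations is not None:
        intervals = [(float(a), float(b)) for a, b in annotations]
        source = "manual_annotation"
    else:
        intervals = _auto_detect_intervals(fv_beats)
        source = "auto_detected"
        if not intervals:
            logger.warning("find_compressions: no compression episodes detected")
            return []
    intervals.sort()
    episodes: list[ThrtEpisode] = []
    prev_end: Optional[float] = None
    for start_s, end_s in intervals:
        if end_s <= start_s:
            raise ValidationError(f"invalid episode interval [{start_s}, {end_s})")
        episodes.append(
            _build_episode(fv_beats, side, start_s, end_s, prev_end, source,
                           baseline_n=baseline_n, post_n=post_n)
        )
        prev_end = end_s
    return episodes


def _auto_detect_intervals(beats: BeatSeries) -> list[tuple[float, float]]:
    sys = beats.systolic
    n = len(sys)
    low = np.zeros(n, dtype=bool)
    # rolling baseline from the 10 most recent beats NOT already flagged as
    # suppressed, so a compression cannot contaminate its own reference
    baseline: list[float] = []
    for i in range(n):
        if len(baseline) >= 3:
            low[i] = bool(
                sys[i] <= 0.70 * float(np.median(baseline)) and beats.valid[i]
            )
        if not low[i] and np.isfinite(sys[i]):
            baseline.append(float(sys[i]))
            if len(baseline) > 10:
                baseline.pop(0)
    # group consecutive low beats into runs, using half a beat interval of
    # margin on each side so intervals cover the true compression edges
    iv = float(np.median(np.diff(beats.onset_s))) if n > 1 else 1.0
    runs: list[tuple[float, float]] = []
    i = 0
    while i < n:
        if low[i]:
            j = i
            while j + 1 < n and low[j + 1]:
                j += 1
            start = beats.onset_s[i] - 0.5 * iv
            end = beats.onset_s[j] + 0.5 * iv
            if AUTO_DURATION_S[0] <= (end - start) <= AUTO_DURATION_S[1]:
                runs.append((float(start), float(end)))
            i = j + 1
        else:
            i += 1
    # merge overlapping or near-contiguous detections (< 2 s apart)
    merged: list[tuple[float, float]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < 2.0:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def compute_thrr(episode: ThrtEpisode, baseline_n: int = 5) -> float:
    """Per-episode ratio: mean of post-release systolic peaks 2-4 over baseline.

    The baseline is the mean systolic velocity of the ``baseline_n`` beats
    immediately preceding compression onset; the first post-release systolic
    peak is ignored and the next three are averaged.
    """
    if len(episode.baseline_systolic) < baseline_n:
        raise ValidationError(
            f"episode needs >= {baseline_n} baseline beats, has "
            f"{len(episode.baseline_systolic)}"
        )
    if len(episode.post_peaks) < 4:
        raise ValidationError(
            f"episode needs >= 4 post-release beats, has {len(episode.post_peaks)}"
        )
    baseline = float(np.mean(episode.baseline_systolic[-baseline_n:]))
    if baseline <= 0:
        raise ValidationError(f"non-positive baseline systolic velocity: {baseline}")
    response = float(np.mean(episode.post_peaks[1:4]))
    return response / baseline


def session_thrr(episodes: Iterable[ThrtEpisode], baseline_n: int = 5) -> ThrrResult:
    """Aggregate episodes into per-side session THRR with QC audit trail.

    Only episodes passing every validity flag enter the side mean; every
    episode is reported with its ratio (when computable) and failed flags.
    A side with no valid episodes yields an explicit not-obtainable outcome.
    """
    episodes = list(episodes)
    audit: list[dict] = []
    per_side: dict[str, list[float]] = {}
    totals: dict[str, int] = {}
    for ep in episodes:
        totals[ep.side] = totals.get(ep.side, 0) + 1
        thrr: Optional[float] = None
        reason = None
        try:
            thrr = compute_thrr(ep, baseline_n=baseline_n)
        except ValidationError as exc:
            reason = str(exc)
        included = ep.all_flags_ok and thrr is not None
        if included:
            per_side.setdefault(ep.side, []).append(thrr)
        audit.append(
            {
                "side": ep.side,
                "start_s": ep.start_s,
                "end_s": ep.end_s,
                "source": ep.source,
                "thrr": thrr,
                "included": included,
                "failed_flags": ep.failed_flags(),
                "exclusion_reason": reason,
            }
        )
    sides: dict[str, SideThrr] = {}
    for side, n_total in totals.items():
        vals = per_side.get(side, [])
        thrr = float(np.mean(vals)) if vals else None
        sides[side] = SideThrr(
            thrr=thrr,
            n_valid=len(vals),
            n_total=n_total,
            classification=classify(thrr),
        )
        if thrr is None:
            logger.info("side %s: THRR not obtainable (0/%d valid episodes)",
                        side, n_total)
    return ThrrResult(sides=sides, episodes=audit)
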