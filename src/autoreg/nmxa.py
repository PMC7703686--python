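"""The nMxa autoregulation index: moving-window correlation of slow waves.

nMxa is the Pearson correlation between slow-wave (0.005-0.05 Hz) changes in
arterial blood pressure and the corresponding changes in cerebral blood-flow
velocity, evaluated over a moving 5-minute window and averaged over the
recording.  Positive correlation means flow passively follows pressure;
a summary value above 0.4 indicates cerebrovascular autoregulatory
dysfunction.  The slow-wave surrogate is the series of 10-s block means
produced by :mod:`autoreg.preprocess`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

from .errors import NotObtainable, ValidationError
from .preprocess import preprocess_recording
from .recording import BlockSeries, WaveformRecording

logger = logging.getLogger(__name__)

#: summary nMxa above this value indicates impaired autoregulation (strict >)
DYSFUNCTION_THRESHOLD = 0.4

SIDE_CHANNEL = {"left": "fvl", "right": "fvr"}


@dataclass
class WindowCorr:
    """One moving-window correlation record."""

    start_s: float
    end_s: float
    n_blocks: int
    r: float


@dataclass
class SideSummary:
    nmxa: Optional[float]
    n_windows: int
    n_windows_skipped: int
    classification: str  # "impaired" | "intact" | "not_obtainable"
    windows: list[WindowCorr] = field(default_factory=list)


@dataclass
class NmxaResult:
    """Per-side and combined summary of the moving-correlation index."""

    sides: dict[str, SideSummary]
    combined: Optional[float]
    window_s: float = 300.0
    step_s: float = 10.0
    obtainable: bool = True

    def to_dict(self) -> dict:
        return {
            "window_s": self.window_s,
            "step_s": self.step_s,
            "obtainable": self.obtainable,
            "combined_nmxa": self.combined,
            "sides": {
                s: {
                    "nmxa": ss.nmxa,
                    "n_windows": ss.n_windows,
                    "n_windows_skipped": ss.n_windows_skipped,
                    "classification": ss.classification,
                }
                for s, ss in sorted(self.sides.items())
            },
        }


def classify(summary: Optional[float]) -> str:
    if summary is None:
        return "not_obtainable"
    return "impaired" if summary > DYSFUNCTION_THRESHOLD else "intact"


def windowed_correlation(
    abp: BlockSeries,
    fv: BlockSeries,
    window_s: float = 300.0,
    step_s: float = 10.0,
    min_blocks: int = 25,
) -> list[WindowCorr]:
    """Pearson correlation of paired valid blocks in each window placement.

    Both series must share the block grid.  Pairs where either block is
    invalid are dropped; windows retaining fewer than ``min_blocks`` pairs,
    or with zero variance on either side, are omitted (logged at debug
    level).  Windows step by ``step_s`` from the start of the block grid.
    """
    if len(abp) != len(fv) or not np.allclose(abp.start_s, fv.start_s):
        raise ValidationError("ABP and FV block series must share the block grid")
    if abp.block_len_s != fv.block_len_s:
        raise ValidationError("ABP and FV block lengths differ")
    if len(abp) == 0:
        return []
    t = abp.start_s
    span = t[-1] + abp.block_len_s - t[0]
    if span < window_s:
        raise ValidationError(
            f"recording span {span:.0f}s shorter than window {window_s:.0f}s"
        )
    pair_valid = abp.valid & fv.valid
    out: list[WindowCorr] = []
    w0 = t[0]
    while w0 + window_s <= t[0] + span + 1e-9:
        in_win = (t >= w0 - 1e-9) & (t < w0 + window_s - 1e-9)
        sel = in_win & pair_valid
        n_sel = int(sel.sum())
        if n_sel < min_blocks:
            logger.debug("window %.0f-%.0f s skipped: only %d valid pairs",
                         w0, w0 + window_s, n_sel)
        else:
            a = abp.value[sel]
            f = fv.value[sel]
            if np.ptp(a) == 0 or np.ptp(f) == 0:
                logger.debug("window %.0f-%.0f s skipped: zero variance", w0,
                             w0 + window_s)
            else:
                r = float(np.corrcoef(a, f)[0, 1])
                out.append(WindowCorr(start_s=float(w0),
                                      end_s=float(w0 + window_s),
                                      n_blocks=n_sel, r=r))
        w0 += step_s
    return out


def nmxa_summary(
    windows_by_side: Mapping[str, Iterable[WindowCorr]],
    n_skipped_by_side: Optional[Mapping[str, int]] = None,
    window_s: float = 300.0,
    step_s: float = 10.0,
) -> NmxaResult:
    """Aggregate window correlations into per-side and combined nMxa.

    The per-side summary is the arithmetic mean of the window r values; the
    combined index is the unweighted mean of the available per-side
    summaries.  Classification is strict: impaired iff summary > 0.4.  A
    side with no valid windows is reported as not obtainable; if no side has
    any, the whole result is flagged not obtainable.
    """
    n_skipped_by_side = n_skipped_by_side or {}
    sides: dict[str, SideSummary] = {}
    for side, wins in windows_by_side.items():
        wins = list(wins)
        if wins:
            val = float(np.mean([w.r for w in wins]))
        else:
            val = None
        sides[side] = SideSummary(
            nmxa=val,
            n_windows=len(wins),
            n_windows_skipped=int(n_skipped_by_side.get(side, 0)),
            classification=classify(val),
            windows=wins,
        )
    avail = [s.nmxa for s in sides.values() if s.nmxa is not None]
    combined = float(np.mean(avail)) if avail else None
    return NmxaResult(
        sides=sides,
        combined=combined,
        window_s=window_s,
        step_s=step_s,
        obtainable=combined is not None,
    )


def nmxa_from_recording(
    rec: WaveformRecording,
    window_s: float = 300.0,
    step_s: float = 10.0,
    min_blocks: int = 25,
    block_len_s: float = 10.0,
    min_valid_frac: float = 0.5,
) -> NmxaResult:
    """Full pipeline: artefact masking, block averaging, moving correlation.

    Requires the ABP channel and at least one flow-velocity channel.  At
    least 30 minutes of data are advisable for a stable index (a warning is
    logged below that); fewer than 5 minutes of analyzable paired data on
    every side is refused.
    """
    if "abp" not in rec.channels:
        raise ValidationError("recording has no ABP channel")
    fv_names = rec.fv_channels()
    if not fv_names:
        raise ValidationError("recording has no flow-velocity channel")
    if rec.duration_s < 1800:
        logger.warning(
            "recording is %.1f min; >= 30 min advisable for a stable nMxa",
            rec.duration_s / 60.0,
        )
    prep = preprocess_recording(rec, block_len_s=block_len_s,
                                min_valid_frac=min_valid_frac)
    abp_blocks = prep.blocks["abp"]
    windows_by_side: dict[str, list[WindowCorr]] = {}
    analyzable: dict[str, float] = {}
    for side, ch in SIDE_CHANNEL.items():
        if ch not in prep.blocks:
            continue
        fv_blocks = prep.blocks[ch]
        pair_valid = abp_blocks.valid & fv_blocks.valid
        analyzable[side] = float(pair_valid.sum()) * block_len_s
        windows_by_side[side] = windowed_correlation(
            abp_blocks, fv_blocks, window_s=window_s, step_s=step_s,
            min_blocks=min_blocks,
        )
    if not analyzable or max(analyzable.values()) < 300.0:
        raise NotObtainable(
            f"fewer than 5 min of analyzable paired data on every side "
            f"(got {analyzable}); nMxa not obtainable"
        )
    logger.info("analyzable paired duration per side: %s",
                {k: f"{v:.0f}s" for k, v in analyzable.items()})
    span = len(abp_blocks) * block_len_s
    n_possible = int((span - window_s) / step_s + 1e-9) + 1 if span >= window_s else 0
    n_skipped = {side: max(0, n_possible - len(w))
                 for side, w in windows_by_side.items()}
    return nmxa_summary(windows_by_side, n_skipped_by_side=n_skipped,
                        window_s=window_s, step_s=step_s)
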