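"""Participant scoring and cohort statistics.

Covers the study-level bookkeeping around the cerebrovascular indices: the
21-item Post-Concussion Symptom Scale total (each item rated 0-6, total out
of 126), median/range group summaries in the pilot's reporting style,
threshold classification of participants, and the projection of the sample
size needed to detect a difference between the healthy mean index (0.21, SD
0.16) and the dysfunction boundary (0.40).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import nmxa, thrt
from .errors import ValidationError

PCSS_N_ITEMS = 21
PCSS_ITEM_MAX = 6  # item scale 0-6, so the total is out of 21*6 = 126


def pcss_total(items: Sequence[int]) -> int:
    """Total of a 21-item symptom-scale response (each item 0-6, total /126)."""
    if len(items) != PCSS_N_ITEMS:
        raise ValidationError(
            f"PCSS response must have exactly {PCSS_N_ITEMS} items, got {len(items)}"
        )
    total = 0
    for i, v in enumerate(items):
        if int(v) != v or not (0 <= int(v) <= PCSS_ITEM_MAX):
            raise ValidationError(
                f"PCSS item {i + 1} must be an integer in [0, {PCSS_ITEM_MAX}], got {v!r}"
            )
        total += int(v)
    return total


@dataclass
class GroupSummary:
    """Median (range, n) summary in the pilot's reporting style."""

    median: Optional[float]
    min: Optional[float]
    max: Optional[float]
    n: int
    n_excluded: int = 0

    def format(self) -> str:
        if self.median is None:
            return f"not obtainable (0 values, {self.n_excluded} excluded)"
        return (f"{self.median:g} (range {self.min:g}-{self.max:g}, "
                f"n = {self.n})")


def summarize_group(values: Iterable[Optional[float]]) -> GroupSummary:
    """Median and range of the finite values; not-obtainable entries are
    excluded from the statistics but counted separately.  The median uses
    the midpoint convention for even n."""
    vals = []
    n_excluded = 0
    for v in values:
        if v is None or (isinstance(v, float) and not math.isfinite(v)):
            n_excluded += 1
        else:
            vals.append(float(v))
    if not vals:
        return GroupSummary(median=None, min=None, max=None, n=0,
                            n_excluded=n_excluded)
    arr = np.asarray(vals)
    return GroupSummary(
        median=float(np.median(arr)),
        min=float(arr.min()),
        max=float(arr.max()),
        n=len(vals),
        n_excluded=n_excluded,
    )


@dataclass
class PowerSpec:
    """Two-sample mean-comparison power specification.

    Defaults encode the projection scenario: healthy mean index 0.21 vs the
    0.40 dysfunction boundary, common SD 0.16, two-sided alpha 0.05, 90%
    power.  ``n_groups`` multiplies the per-group n into a total.
    """

    mu0: float = 0.21
    mu1: float = 0.40
    sd: float = 0.16
    alpha: float = 0.05
    power: float = 0.90
    n_groups: int = 2

    def validate(self) -> "PowerSpec":
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0 < self.power < 1:
            raise ValidationError(f"power must be in (0,1), got {self.power}")
        if self.sd <= 0:
            raise ValidationError(f"sd must be > 0, got {self.sd}")
        if self.mu0 == self.mu1:
            raise ValidationError("mu0 and mu1 must differ")
        if self.n_groups < 1:
            raise ValidationError("n_groups must be >= 1")
        return self


def power_sample_size(spec: PowerSpec) -> tuple[int, int]:
    """Per-group and total n for a two-sided two-sample comparison of means.

    Normal approximation n = 2 sd^2 (z_{1-a/2} + z_{power})^2 / delta^2 with
    a +1 correction for the t-distribution, rounded up.
    """
    spec.validate()
    delta = abs(spec.mu1 - spec.mu0)
    z_a = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    z_b = stats.norm.ppf(spec.power)
    raw = 2.0 * spec.sd**2 * (z_a + z_b) ** 2 / delta**2
    n_per_group = int(math.ceil(raw + 1.0))
    return n_per_group, n_per_group * spec.n_groups


@dataclass
class ParticipantRecord:
    """One participant's metrics; absent metrics are not-obtainable."""

    group: str  # "control" | "tbi"
    nmxa: Optional[float] = None
    thrr_left: Optional[float] = None
    thrr_right: Optional[float] = None
    pcss: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("control", "tbi"):
            raise ValidationError(f"unknown group {self.group!r}")
        for name in ("nmxa", "thrr_left", "thrr_right"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(float(v)):
                raise ValidationError(f"{name} must be finite when present")


def classify_participant(rec: ParticipantRecord) -> dict[str, str]:
    """Threshold labels: nMxa impaired iff > 0.4; THRR preserved iff >= 1.10."""
    if rec.nmxa is None and rec.thrr_left is None and rec.thrr_right is None:
        return {
            "nmxa": "not_obtainable",
            "thrr_left": "not_obtainable",
            "thrr_right": "not_obtainable",
        }
    return {
        "nmxa": nmxa.classify(rec.nmxa),
        "thrr_left": thrt.classify(rec.thrr_left),
        "thrr_right": thrt.classify(rec.thrr_right),
    }


METRIC_COLUMNS = ("nmxa", "thrr_left", "thrr_right", "pcss")


def cohort_report(participants: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Group-by-metric summary table in median (range, n) style."""
    rows = []
    parts = list(participants)
    for group in sorted({p.group for p in parts}):
        members = [p for p in parts if p.group == group]
        for metric in METRIC_COLUMNS:
            s = summarize_group(getattr(p, metric) for p in members)
            rows.append(
                {
                    "group": group,
                    "metric": metric,
                    "summary": s.format(),
                    "median": s.median,
                    "min": s.min,
                    "max": s.max,
                    "n": s.n,
                    "n_excluded": s.n_excluded,
                }
            )
    return pd.DataFrame(rows)
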