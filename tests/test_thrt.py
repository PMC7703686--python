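"""Hyperaemic response test: segmentation, ratio, QC flags."""

import numpy as np
import pytest

from autoreg import (SimulationConfig, ThrtSimSpec, ValidationError,
                     compute_thrr, detect_beats, find_compressions,
                     session_thrr, synth_thrt_session)
from autoreg.recording import BeatSeries
from autoreg.thrt import ThrtEpisode, classify

from _oracles import thrr_exclude_first_oracle


def _episode(baseline, post, nadir=40.0, side="left", start=100.0, end=106.0,
             flags=None):
    defaults = {"drop_ok": True, "duration_ok": True, "spacing_ok": True,
                "signal_ok": True}
    return ThrtEpisode(
        side=side, start_s=start, end_s=end,
        baseline_systolic=np.asarray(baseline, float),
        nadir_systolic=nadir,
        post_peaks=np.asarray(post, float),
        flags=defaults | (flags or {}),
    )


def test_thrr_hand_computed_example():
    """Baseline 60s, post peaks {80, 66, 69, 72}: the exaggerated first peak
    is ignored, response = (66+69+72)/3 = 69, THRR = 1.15."""
    ep = _episode([60, 60, 60, 60, 60], [80, 66, 69, 72])
    assert compute_thrr(ep) == pytest.approx(1.15)
    assert classify(compute_thrr(ep)) == "preserved"


def test_thrr_no_hyperaemia_is_unity():
    ep = _episode([60] * 5, [60, 60, 60, 60])
    assert compute_thrr(ep) == pytest.approx(1.0)


def test_thrr_equals_exclude_first_oracle():
    rng = np.random.default_rng(5)
    for _ in range(20):
        baseline = list(rng.uniform(50, 70, 5))
        post = list(rng.uniform(55, 85, 6))
        ep = _episode(baseline, post)
        assert compute_thrr(ep) == pytest.approx(
            thrr_exclude_first_oracle(baseline, post), abs=1e-12)


def test_first_peak_exclusion_matters():
    """Including the exaggerated first peak would change the ratio."""
    baseline = [60.0] * 5
    post = [90.0, 66.0, 69.0, 72.0]
    ep = _episode(baseline, post)
    with_first = np.mean(post[:3]) / 60.0
    assert compute_thrr(ep) != pytest.approx(with_first)
    assert compute_thrr(ep) == pytest.approx(1.15)


def test_preserved_threshold_inclusive():
    assert classify(1.10) == "preserved"
    assert classify(1.09) == "impaired"


def test_thrr_scale_invariance():
    ep1 = _episode([60] * 5, [80, 66, 69, 72])
    ep2 = _episode([x * 2.5 for x in [60] * 5],
                   [x * 2.5 for x in [80, 66, 69, 72]])
    assert compute_thrr(ep1) == pytest.approx(compute_thrr(ep2), abs=1e-12)


def test_thrr_insufficient_beats_rejected():
    with pytest.raises(ValidationError, match="baseline"):
        compute_thrr(_episode([60, 60], [80, 66, 69, 72]))
    with pytest.raises(ValidationError, match="post-release"):
        compute_thrr(_episode([60] * 5, [80, 66]))
    with pytest.raises(ValidationError, match="baseline"):
        compute_thrr(_episode([0.0] * 5, [80, 66, 69, 72]))


# --- session aggregation ----------------------------------------------------

def test_session_mean_of_valid_episodes():
    eps = [
        _episode([60] * 5, [70, 67.8, 67.8, 67.8]),   # 1.13
        _episode([60] * 5, [70, 70.2, 70.2, 70.2], start=200, end=206),  # 1.17
    ]
    res = session_thrr(eps)
    assert res.sides["left"].thrr == pytest.approx(1.15)
    assert res.sides["left"].classification == "preserved"


def test_session_excludes_flagged_episodes():
    eps = [
        _episode([60] * 5, [75, 72, 72, 72]),  # 1.20 valid
        _episode([60] * 5, [90, 84, 84, 84], start=200, end=206,
                 flags={"drop_ok": False}),  # 1.40 invalid
    ]
    res = session_thrr(eps)
    assert res.sides["left"].thrr == pytest.approx(1.20)
    assert res.sides["left"].n_valid == 1
    audit = [e for e in res.episodes if not e["included"]]
    assert audit and audit[0]["failed_flags"] == ["drop_ok"]


def test_session_all_invalid_not_obtainable():
    eps = [_episode([60] * 5, [70, 70, 70, 70],
                    flags={"signal_ok": False})]
    res = session_thrr(eps)
    assert res.sides["left"].thrr is None
    assert res.sides["left"].classification == "not_obtainable"
    assert res.episodes[0]["failed_flags"] == ["signal_ok"]


# --- segmentation on synthetic sessions -------------------------------------

@pytest.fixture(scope="module")
def thrt_session():
    cfg = SimulationConfig(duration_s=360.0, seed=3)
    return synth_thrt_session(cfg, ThrtSimSpec())


def test_autodetect_recovers_truth_intervals(thrt_session):
    rec, truth = thrt_session
    found = {}
    for side, ch in (("left", "fvl"), ("right", "fvr")):
        beats = detect_beats(rec.channels[ch], rec.fs, rec.masks[ch])
        found[side] = find_compressions(beats, side=side)
    for t in truth:
        eps = found[t["side"]]
        overlaps = []
        for e in eps:
            lo = max(e.start_s, t["start_s"])
            hi = min(e.end_s, t["end_s"])
            overlaps.append(max(0.0, hi - lo) / (t["end_s"] - t["start_s"]))
        assert max(overlaps) >= 0.8, t


def test_autodetect_episode_flags_all_pass(thrt_session):
    rec, _ = thrt_session
    beats = detect_beats(rec.channels["fvl"], rec.fs)
    eps = find_compressions(beats, side="left")
    assert len(eps) == 2
    for e in eps:
        assert e.all_flags_ok, e.flags


def test_annotated_weak_drop_flagged():
    """A compression with only a 25% systolic drop fails the >30% rule."""
    cfg = SimulationConfig(duration_s=360.0, seed=4)
    spec = ThrtSimSpec(drop_frac=0.25)
    rec, truth = synth_thrt_session(cfg, spec)
    beats = detect_beats(rec.channels["fvl"], rec.fs)
    ivals = [(t["start_s"], t["end_s"]) for t in truth if t["side"] == "left"]
    eps = find_compressions(beats, annotations=ivals, side="left")
    assert all(not e.flags["drop_ok"] for e in eps)
    assert all(e.source == "manual_annotation" for e in eps)


def test_close_spacing_flagged():
    """Two compressions 30 s apart: the second fails the 1-min spacing rule."""
    cfg = SimulationConfig(duration_s=360.0, seed=5)
    rec, truth = synth_thrt_session(cfg, ThrtSimSpec(n_compressions=1))
    beats = detect_beats(rec.channels["fvl"], rec.fs)
    t0, t1 = truth[0]["start_s"], truth[0]["end_s"]
    eps = find_compressions(
        beats, annotations=[(t0, t1), (t1 + 30.0, t1 + 36.0)], side="left")
    assert eps[0].flags["spacing_ok"]
    assert not eps[1].flags["spacing_ok"]


def test_parameter_recovery_overshoot():
    """Estimated session THRR within 0.02 of 1 + overshoot across seeds."""
    spec = ThrtSimSpec(overshoot_frac=0.15)
    vals = []
    for s in range(50):
        cfg = SimulationConfig(duration_s=360.0, seed=s)
        rec, truth = synth_thrt_session(cfg, spec)
        eps = []
        for side, ch in (("left", "fvl"), ("right", "fvr")):
            beats = detect_beats(rec.channels[ch], rec.fs)
            ivals = [(t["start_s"], t["end_s"]) for t in truth
                     if t["side"] == side]
            eps += find_compressions(beats, annotations=ivals, side=side)
        res = session_thrr(eps)
        side_vals = [v.thrr for v in res.sides.values() if v.thrr is not None]
        vals.append(float(np.mean(side_vals)))
    assert abs(float(np.mean(vals)) - 1.15) < 0.02


def test_empty_beat_series_yields_no_episodes():
    empty = BeatSeries(onset_s=np.empty(0), systolic=np.empty(0),
                       diastolic=np.empty(0), mean=np.empty(0),
                       valid=np.empty(0, dtype=bool))
    assert find_compressions(empty, side="left") == []
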