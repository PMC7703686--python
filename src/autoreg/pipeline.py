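"""End-to-end run: waveform file -> artefact removal -> nMxa (+ THRR) report.

``run_pipeline`` composes the preprocessing, moving-correlation and
hyperaemic-response modules, then writes a machine-readable JSON result and a
human-readable text report.  Outputs embed the effective configuration digest
and seed, and are written only after all computation succeeds, so a failing
run leaves no partial outputs.  Two runs on identical inputs and
configuration produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from . import nmxa as nmxa_mod
from . import thrt as thrt_mod
from .errors import NotObtainable, ValidationError
from .preprocess import detect_beats
from .recording import WaveformRecording
from .waveio import read_annotations, read_waveform

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_ERROR = 1
EXIT_NOT_OBTAINABLE = 2


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults; unknown keys rejected."""

    window_s: float = 300.0
    step_s: float = 10.0
    min_blocks: int = 25
    block_len_s: float = 10.0
    min_valid_frac: float = 0.5
    baseline_n: int = 5
    auto_detect_thrt: bool = False
    seed: int = 0
    out_dir: str = "."
    verbosity: str = "info"

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValidationError(
                f"unknown config keys: {sorted(unknown)} (known: {sorted(known)})"
            )
        return cls(**data)

    def digest(self) -> str:
        payload = asdict(self)
        # where outputs land and how chatty the run is do not affect results
        payload.pop("out_dir", None)
        payload.pop("verbosity", None)
        blob = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    nmxa_result: Optional[nmxa_mod.NmxaResult]
    thrr_result: Optional[thrt_mod.ThrrResult]
    exit_status: int
    messages: list[str] = field(default_factory=list)

    def to_dict(self, config: RunConfig) -> dict:
        return {
            "config_digest": config.digest(),
            "seed": config.seed,
            "config": asdict(config),
            "nmxa": self.nmxa_result.to_dict() if self.nmxa_result else None,
            "thrr": self.thrr_result.to_dict() if self.thrr_result else None,
            "messages": self.messages,
        }


def _render_report(bundle: ReportBundle, config: RunConfig) -> str:
    lines = [
        "cerebral autoregulation report",
        f"config digest: {config.digest()}  seed: {config.seed}",
        "",
    ]
    if bundle.nmxa_result is not None and bundle.nmxa_result.obtainable:
        res = bundle.nmxa_result
        lines.append(f"nMxa (moving {res.window_s:.0f}-s window, "
                     f"step {res.step_s:.0f} s):")
        for side, ss in sorted(res.sides.items()):
            if ss.nmxa is None:
                lines.append(f"  {side:>5}: not obtainable "
                             f"({ss.n_windows} valid windows)")
            else:
                lines.append(
                    f"  {side:>5}: nMxa = {ss.nmxa:+.3f} "
                    f"({ss.classification}; {ss.n_windows} windows, "
                    f"{ss.n_windows_skipped} skipped)"
                )
        lines.append(f"  combined: {res.combined:+.3f} "
                     f"({nmxa_mod.classify(res.combined)}, threshold > "
                     f"{nmxa_mod.DYSFUNCTION_THRESHOLD})")
    else:
        lines.append("nMxa: not obtainable")
    lines.append("")
    if bundle.thrr_result is not None and bundle.thrr_result.sides:
        lines.append("THRR (post-release systolic peaks 2-4 over baseline):")
        for side, sv in sorted(bundle.thrr_result.sides.items()):
            if sv.thrr is None:
                lines.append(f"  {side:>5}: not obtainable "
                             f"({sv.n_valid}/{sv.n_total} valid episodes)")
            else:
                lines.append(
                    f"  {side:>5}: THRR = {sv.thrr:.3f} ({sv.classification}, "
                    f"threshold >= {thrt_mod.PRESERVED_THRESHOLD}; "
                    f"{sv.n_valid}/{sv.n_total} episodes)"
                )
    else:
        lines.append("THRR: not obtainable (no annotations, auto-detect off, "
                     "or no episodes found)")
    for msg in bundle.messages:
        lines.append(f"note: {msg}")
    return "\n".join(lines) + "\n"


def run_pipeline(
    config: RunConfig,
    waveform_path: Union[str, Path],
    annotations_path: Optional[Union[str, Path]] = None,
    write_outputs: bool = True,
) -> ReportBundle:
    """Execute the full analysis on a waveform file.

    Returns a :class:`ReportBundle` whose ``exit_status`` distinguishes
    success (0), not-obtainable metrics (2), and errors (raised).  With
    ``write_outputs`` the bundle is written as ``nmxa_result.json``,
    ``thrr_result.json`` and ``report.txt`` under ``config.out_dir``.
    """
    rec = read_waveform(waveform_path)
    messages: list[str] = []

    nmxa_result: Optional[nmxa_mod.NmxaResult] = None
    try:
        nmxa_result = nmxa_mod.nmxa_from_recording(
            rec,
            window_s=config.window_s,
            step_s=config.step_s,
            min_blocks=config.min_blocks,
            block_len_s=config.block_len_s,
            min_valid_frac=config.min_valid_frac,
        )
    except NotObtainable as exc:
        messages.append(f"nmxa: {exc}")

    thrr_result: Optional[thrt_mod.ThrrResult] = None
    annotations = None
    if annotations_path is not None:
        annotations = read_annotations(annotations_path)
    if annotations is not None or config.auto_detect_thrt:
        episodes: list[thrt_mod.ThrtEpisode] = []
        for side, ch in nmxa_mod.SIDE_CHANNEL.items():
            if ch not in rec.channels:
                continue
            beats = detect_beats(rec.channels[ch], rec.fs, rec.masks[ch])
            if annotations is not None:
                ivals = [(a["start_s"], a["end_s"]) for a in annotations
                         if a["side"] == side]
                if not ivals:
                    continue
                episodes += thrt_mod.find_compressions(
                    beats, annotations=ivals, side=side,
                    baseline_n=config.baseline_n)
            else:
                episodes += thrt_mod.find_compressions(
                    beats, side=side, baseline_n=config.baseline_n)
        if episodes:
            thrr_result = thrt_mod.session_thrr(episodes,
                                                baseline_n=config.baseline_n)
        else:
            messages.append("thrr: no compression episodes found")

    nmxa_ok = nmxa_result is not None and nmxa_result.obtainable
    thrr_ok = thrr_result is not None and any(
        s.thrr is not None for s in thrr_result.sides.values())
    thrr_requested = annotations is not None or config.auto_detect_thrt
    status = EXIT_OK
    if not nmxa_ok or (thrr_requested and not thrr_ok):
        status = EXIT_NOT_OBTAINABLE
    bundle = ReportBundle(nmxa_result=nmxa_result, thrr_result=thrr_result,
                          exit_status=status, messages=messages)

    if write_outputs:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = bundle.to_dict(config)
        with open(out / "nmxa_result.json", "w") as fh:
            json.dump({k: payload[k] for k in
                       ("config_digest", "seed", "nmxa")}, fh,
                      indent=2, sort_keys=True)
        with open(out / "thrr_result.json", "w") as fh:
            json.dump({k: payload[k] for k in
                       ("config_digest", "seed", "thrr")}, fh,
                      indent=2, sort_keys=True)
        with open(out / "report.txt", "w") as fh:
            fh.write(_render_report(bundle, config))
    return bundle
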