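"""End-to-end orchestration: segment -> metrics -> quorum -> stats.

A pipeline run is configured by a flat key-value document (YAML); every
stage reads and writes the file formats defined in :mod:`collmove.io`, and
a run manifest records the config hash, seed, package version and every
file written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__ as version
from . import io as cmio
from .battery import run_test_battery
from .networks import compute_dai, compute_hwi, eigenvector_centrality, mean_joining_order
from .quorum import build_curve, detect_lower_threshold, detect_upper_threshold, simple_majority
from .segmentation import SegmentationParams, segment_session
from .simulate import SimulationConfig, simulate_study
from .types import ValidationError, adults

log = logging.getLogger("collmove")

_ANALYSIS_SWITCHES = {
    "hwi_variant": ("ratio", "whitehead"),
    "n_convention": ("joiners", "group"),
    "kw_replicate_unit": ("jackknife", "joining_order"),
}


@dataclass
class PipelineConfig:
    """Paths, segmentation overrides and analysis switches for one run."""

    roster: str | None = None
    fixes: str | None = None
    bouts: str | None = None
    events: str | None = None  # pre-segmented events; skips segmentation
    out_dir: str = "out"
    seed: int = 0
    hwi_variant: str = "ratio"
    use_all_joiners: bool = False
    n_convention: str = "joiners"
    kw_replicate_unit: str = "jackknife"
    min_support: int = 5
    segmentation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, allowed in _ANALYSIS_SWITCHES.items():
            if getattr(self, key) not in allowed:
                raise ValidationError(
                    f"config: {key} must be one of {allowed}, got {getattr(self, key)!r}"
                )
        valid_seg = {f.name for f in dc_fields(SegmentationParams)}
        unknown = set(self.segmentation) - valid_seg
        if unknown:
            raise ValidationError(f"config: unknown segmentation key(s) {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"config: unknown key(s) {sorted(unknown)}")
        return cls(**raw)

    def params(self) -> SegmentationParams:
        return SegmentationParams(**self.segmentation)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(
        {f.name: getattr(config, f.name) for f in dc_fields(config)},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_all(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns the manifest.

    Any stage failure raises with the stage name in the message.  Every
    output file is declared in the manifest; no undeclared writes happen.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def _write(name: str, writer) -> None:
        path = out / name
        writer(path)
        written.append(name)
        log.info("stage=write file=%s", name)

    if config.roster is None:
        raise ValidationError("stage=input: a roster path is required")
    roster = cmio.read_roster(config.roster)
    params = config.params()

    log.info("stage=segment")
    if config.events is not None:
        events = cmio.read_events(config.events)
    elif config.fixes is not None:
        fixes = cmio.read_fixes(config.fixes, roster)
        events = segment_session(fixes, roster, params)
    else:
        raise ValidationError("stage=segment: either fixes or events must be given")
    if not events:
        raise ValidationError("stage=segment: no movement events found")
    _write("events.json", lambda p: cmio.write_events(events, p))

    log.info("stage=metrics n_events=%d", len(events))
    adult_ids = [r.id for r in adults(roster)]
    hwi = compute_hwi(
        events, adult_ids,
        use_all_joiners=config.use_all_joiners, variant=config.hwi_variant,
    )
    _write("hwi.csv", lambda p: cmio.write_matrix(hwi, p))
    cent_hwi = eigenvector_centrality(hwi)
    _write("centrality_hwi.csv", lambda p: cmio.write_matrix(cent_hwi, p))

    cent_dai = None
    if config.bouts is not None:
        bouts = cmio.read_bouts(config.bouts, roster)
        dai = compute_dai(bouts, roster, adult_ids)
        _write("dai.csv", lambda p: cmio.write_matrix(dai, p))
        cent_dai = eigenvector_centrality(dai)
        _write("centrality_dai.csv", lambda p: cmio.write_matrix(cent_dai, p))

    orders = {
        i: mean_joining_order(events, i, config.n_convention, group_size=len(roster))
        for i in adult_ids
    }
    import pandas as pd

    _write(
        "joining_order.csv",
        lambda p: pd.DataFrame(
            {"id": list(orders), "mean_joining_order": list(orders.values())}
        ).to_csv(p, index=False, float_format="%.17g"),
    )

    log.info("stage=quorum")
    curve = build_curve(events)
    _write("curve.csv", lambda p: curve.to_frame().to_csv(p, index=False, float_format="%.17g"))
    report = {
        "upper_threshold": detect_upper_threshold(curve, config.min_support),
        "lower_threshold": detect_lower_threshold(curve, config.min_support),
        "min_support": config.min_support,
        "n_events": int(curve.n_events.sum()),
        "simple_majority_adults": simple_majority(len(adult_ids)),
    }
    _write("quorum_report.json", lambda p: p.write_text(json.dumps(report, indent=1)))

    log.info("stage=stats")
    stats_report = run_test_battery(
        roster, events, cent_hwi, cent_dai,
        kw_replicate_unit=config.kw_replicate_unit,
        n_convention=config.n_convention,
    )
    _write("stats.json", lambda p: p.write_text(json.dumps(stats_report, indent=1)))

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": version,
        "numpy": np.__version__,
        "outputs": written,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("stage=done outputs=%d", len(written) + 1)
    return manifest


def demo_fixture(seed: int = 42, n_events: int = 20):
    """A packaged small dataset for docs and smoke tests.

    Returns (roster, events, bouts): the group of 32 around the packaged
    12-adult roster, with a seeded 20-event synthetic session under the
    quorum rule.
    """
    config = SimulationConfig(rule="quorum", n_events=n_events, seed=seed)
    study = simulate_study(config)
    return study.roster, study.events, study.bouts
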