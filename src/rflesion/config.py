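"""Plain-text (YAML) configuration: metric constants, index targets and
processing/exclusion thresholds.

The config file makes every stand-in constant explicit — nothing in the
package hard-codes "the" index coefficients — and lets an alternative AI
exponent nesting or filter alignment be selected without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .metrics import AIConstants, LSIConstants, MetricConstants, calibrate_constants

__all__ = ["PipelineConfig", "load_config", "save_config", "default_config"]


@dataclass
class PipelineConfig:
    constants: MetricConstants
    ai_target: float = 400.0
    lsi_target: float = 4.0
    fs_hz: float = 997.0
    filter_window_s: float = 1.5
    filter_mode: str = "centered"
    cf_window_s: float = 6.0
    max_duration_s: float = 30.0
    max_ild_mm: float = 6.0


def default_config() -> PipelineConfig:
    """Study-condition defaults: constants calibrated so the oracles cross
    AI = 400 at 7 s and LSI = 4 at 20 s under the reference inputs."""
    return PipelineConfig(constants=calibrate_constants())


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    ai, lsi = cfg.constants.ai, cfg.constants.lsi
    doc = {
        "ai_constants": {k: float(v) for k, v in
                         (("K", ai.K), ("a", ai.a), ("b", ai.b), ("c", ai.c))},
        "lsi_constants": {k: float(v) for k, v in
                          (("b0", lsi.b0), ("b1", lsi.b1), ("b2", lsi.b2),
                           ("b3", lsi.b3), ("b4", lsi.b4), ("b5", lsi.b5))},
        "targets": {"ai": cfg.ai_target, "lsi": cfg.lsi_target},
        "processing": {
            "fs_hz": cfg.fs_hz,
            "filter_window_s": cfg.filter_window_s,
            "filter_mode": cfg.filter_mode,
            "cf_window_s": cfg.cf_window_s,
        },
        "exclusions": {"max_duration_s": cfg.max_duration_s, "max_ild_mm": cfg.max_ild_mm},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text())
    constants = MetricConstants(
        ai=AIConstants(**doc["ai_constants"]),
        lsi=LSIConstants(**doc["lsi_constants"]),
    )
    targets = doc.get("targets", {})
    proc = doc.get("processing", {})
    excl = doc.get("exclusions", {})
    return PipelineConfig(
        constants=constants,
        ai_target=float(targets.get("ai", 400.0)),
        lsi_target=float(targets.get("lsi", 4.0)),
        fs_hz=float(proc.get("fs_hz", 997.0)),
        filter_window_s=float(proc.get("filter_window_s", 1.5)),
        filter_mode=str(proc.get("filter_mode", "centered")),
        cf_window_s=float(proc.get("cf_window_s", 6.0)),
        max_duration_s=float(excl.get("max_duration_s", 30.0)),
        max_ild_mm=float(excl.get("max_ild_mm", 6.0)),
    )
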