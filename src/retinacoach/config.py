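"""Run configuration and artifact plumbing shared by the CLI verbs.

A run configuration is a YAML/JSON document with one optional section per
subsystem (``curation``, ``model``, ``difficulty``, ``engine``,
``simulation``) plus a top-level ``seed`` and ``paths``.  Sections are
validated against the corresponding dataclass fields — unknown keys are
rejected by name, so typos fail loudly instead of silently using defaults.

``write_artifacts`` persists a run's outputs with a manifest of file names,
sizes and SHA-256 checksums, and the decision log as JSONL.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Mapping, Optional, Sequence

import yaml

from .allocation import AllocationDecision, EngineConfig, write_decision_log
from .contrastive import TrainConfig
from .simulator import SimConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "write_artifacts"]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A malformed run configuration; the message names the offending key."""


@dataclass
class CurationConfig:
    min_count: int = 50
    train_fraction: float = 0.8
    n_images: int = 2000
    co_occurrence: float = 0.15
    exclusion_list: Optional[str] = None  # manual bad-quality exclusions


@dataclass
class DifficultyConfig:
    k: int = 9
    calibration_path: Optional[str] = None
    prob_bounds: Optional[list] = None  # fixed-bound fallback
    neighbor_bounds: Optional[list] = None


@dataclass
class RunConfig:
    seed: int = 0
    paths: Dict[str, str] = field(default_factory=dict)
    curation: CurationConfig = field(default_factory=CurationConfig)
    model: TrainConfig = field(default_factory=TrainConfig)
    difficulty: DifficultyConfig = field(default_factory=DifficultyConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)
    simulation: SimConfig = field(default_factory=SimConfig)

    def to_dict(self) -> dict:
        out: Dict[str, Any] = {"seed": self.seed, "paths": dict(self.paths)}
        for section in ("curation", "model", "difficulty", "engine",
                        "simulation"):
            out[section] = dataclasses.asdict(getattr(self, section))
        return out


def _build(cls, doc: Mapping[str, Any], section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(doc) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section {section!r}"
        )
    try:
        return cls(**doc)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {section!r}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration file."""
    text = Path(path).read_text(encoding="utf-8")
    doc = yaml.safe_load(text) or {}
    if not isinstance(doc, dict):
        raise ConfigError("configuration root must be a mapping")
    sections = {
        "curation": CurationConfig,
        "model": TrainConfig,
        "difficulty": DifficultyConfig,
        "engine": EngineConfig,
        "simulation": SimConfig,
    }
    known = set(sections) | {"seed", "paths"}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    kwargs: Dict[str, Any] = {
        "seed": doc.get("seed", 0),
        "paths": doc.get("paths", {}) or {},
    }
    for name, cls in sections.items():
        sub = doc.get(name, {}) or {}
        # tuples serialise as lists; coerce back for dataclass fields
        for f in dataclasses.fields(cls):
            if f.name in sub and isinstance(sub[f.name], list) \
                    and "Tuple" in str(f.type):
                sub[f.name] = tuple(sub[f.name])
        kwargs[name] = _build(cls, sub, name)
    cfg = RunConfig(**kwargs)
    log.info("effective configuration: %s", json.dumps(cfg.to_dict(),
                                                       default=str))
    return cfg


def write_artifacts(out_dir,
                    report: Optional[Mapping[str, Any]] = None,
                    decisions: Sequence[AllocationDecision] = (),
                    files: Optional[Mapping[str, str]] = None) -> dict:
    """Write run outputs plus a checksum manifest; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if report is not None:
        p = out / "report.json"
        p.write_text(json.dumps(report, indent=1, sort_keys=True),
                     encoding="utf-8")
        written.append(p)
    if decisions:
        p = out / "decisions.jsonl"
        write_decision_log(decisions, p)
        written.append(p)
    for name, content in (files or {}).items():
        p = out / name
        p.write_text(content, encoding="utf-8")
        written.append(p)
    manifest = {
        "schema_version": "1",
        "n_decisions": len(decisions),
        "files": [
            {
                "name": p.name,
                "bytes": p.stat().st_size,
                "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
            }
            for p in written
        ],
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")
    return manifest
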