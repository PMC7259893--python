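"""Configuration loading, fixture emission and result serialization.

YAML is the configuration format (sections: scenario, animal, physiology,
diet, experiment); CSV is the canonical numeric output.  A JSON run manifest
accompanies every output directory so runs are reproducible byte-for-byte.
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from . import config as cfg
from .config import SCENARIO_NAMES, build_diet, build_scenario
from .morphometry import TAXA, build_animal

__all__ = ["load_config", "save_yaml", "write_fixtures", "write_manifest"]


def save_yaml(obj, path: Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(obj), sort_keys=True))


def load_config(path: Path) -> dict:
    """Load a YAML config file; recognized sections are materialized into
    the package's dataclasses, everything else passes through."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = dict(raw)
    if "scenario" in raw:
        sc = raw["scenario"]
        out["scenario"] = (build_scenario(sc) if isinstance(sc, str)
                           else cfg.scenario_from_dict(sc))
    if "physiology" in raw:
        out["physiology"] = cfg.physiology_from_dict(raw["physiology"])
    if "diet" in raw:
        d = raw["diet"]
        out["diet"] = build_diet(d) if isinstance(d, str) else cfg.diet_from_dict(d)
    return out


def write_fixtures(out_dir: Path) -> list[Path]:
    """Emit every named scenario, diet and taxon spec as YAML files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in SCENARIO_NAMES:
        p = out_dir / f"scenario_{name}.yaml"
        save_yaml(build_scenario(name), p)
        written.append(p)
    for name in ("high_browser", "low_browser", "carnivore"):
        p = out_dir / f"diet_{name}.yaml"
        save_yaml(build_diet(name), p)
        written.append(p)
    for taxon in TAXA:
        animal = build_animal(taxon)
        p = out_dir / f"animal_{taxon}.yaml"
        save_yaml(animal, p)
        written.append(p)
    return written


def write_manifest(out_dir: Path, experiment: str, config_snapshot: dict,
                   outputs: list[str]) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = dict(
        package="paleotherm",
        version=__version__,
        python=platform.python_version(),
        timestamp=datetime.now(timezone.utc).isoformat(),
        experiment=experiment,
        config=config_snapshot,
        outputs=outputs,
    )
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
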