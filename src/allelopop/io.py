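"""CSV writers, run manifests and structured output for simulation runs."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from .config import ModelConfig, config_hash, dump_config
from .engine import PopulationSnapshot

SNAPSHOT_COLUMNS = ["time_h", "cell_id", "type", "n1", "n2", "n_total", "r_total", "v"]


def write_snapshot(snapshot: PopulationSnapshot, path) -> Path:
    """Write one snapshot as CSV with the fixed column layout."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = snapshot.to_frame()[SNAPSHOT_COLUMNS]
    frame.to_csv(path, index=False)
    return path


def read_snapshot(path) -> pd.DataFrame:
    """Read a snapshot CSV back into a DataFrame (columns as written)."""
    frame = pd.read_csv(path)
    missing = [c for c in SNAPSHOT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"snapshot file {path} is missing column(s): {', '.join(missing)}")
    return frame


def write_summary(stats: dict, path) -> Path:
    """Write named scalar statistics as a two-column CSV (sorted by name)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        {"statistic": sorted(stats), "value": [stats[k] for k in sorted(stats)]}
    )
    frame.to_csv(path, index=False)
    return path


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a run bit-exactly."""

    scenario: str
    seed: int
    config_hash: str
    t_start_h: float
    t_end_h: float
    version: str
    parameters: dict

    @classmethod
    def for_run(cls, config: ModelConfig, scenario: str, seed: int, **parameters) -> "RunManifest":
        from . import __version__

        return cls(
            scenario=scenario,
            seed=seed,
            config_hash=config_hash(config),
            t_start_h=0.0,
            t_end_h=config.sim.t_end,
            version=__version__,
            parameters=parameters,
        )


def write_manifest(manifest: RunManifest, config: ModelConfig, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.toml").write_text(dump_config(config))
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(asdict(manifest), indent=2, sort_keys=True) + "\n")
    return path
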