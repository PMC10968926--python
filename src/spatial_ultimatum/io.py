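"""CSV output with provenance headers.

Every file starts with ``#``-prefixed comment lines naming the package
version and the resolved parameters, so CSV parsers can skip them
(``pd.read_csv(..., comment="#")``) and reruns with identical inputs
produce byte-identical files (no timestamps).
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import __version__
from .config import RunConfig, write_config
from .engine import GameParams
from .experiments import ScenarioSummary, summary_frame
from .lattice import PopulationState, snapshot_frame
from .metrics import MetricsRecord

__all__ = [
    "trajectory_frame",
    "write_trajectory",
    "write_summary",
    "write_snapshot",
    "write_outputs",
]


def _provenance_lines(params: GameParams | None, extra: Mapping | None = None) -> str:
    items: dict = {"package": f"spatial-ultimatum {__version__}"}
    if params is not None:
        d = asdict(params)
        d["deltas"] = {str(k): v for k, v in dict(params.deltas).items()} or "{}"
        items.update(d)
    items.update(extra or {})
    return "".join(f"# {k}: {v}\n" for k, v in items.items())


def _write_frame(df: pd.DataFrame, path: Path, header: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, lineterminator="\n")


def trajectory_frame(records: Iterable[MetricsRecord]) -> pd.DataFrame:
    """Metrics trajectory as a tidy frame, one row per time step."""
    return pd.DataFrame([r.to_row() for r in records])


def write_trajectory(
    records: Iterable[MetricsRecord],
    path: str | Path,
    params: GameParams | None = None,
    seed: int | None = None,
) -> None:
    extra = {} if seed is None else {"seed": seed}
    _write_frame(trajectory_frame(records), Path(path), _provenance_lines(params, extra))


def write_summary(
    summaries: list[ScenarioSummary], path: str | Path, master_seed: int | None = None
) -> None:
    extra = {} if master_seed is None else {"master_seed": master_seed}
    _write_frame(summary_frame(summaries), Path(path), _provenance_lines(None, extra))


def write_snapshot(
    state: PopulationState, path: str | Path, params: GameParams | None = None
) -> None:
    _write_frame(snapshot_frame(state), Path(path), _provenance_lines(params, {"t": state.time}))


def write_outputs(
    out_dir: str | Path,
    cfg: RunConfig,
    trajectories: Mapping[int, list[MetricsRecord]],
    summaries: list[ScenarioSummary] | None = None,
    snapshots: Mapping[tuple[int, int], PopulationState] | None = None,
    scenario_id: str = "run",
) -> list[Path]:
    """Write trajectory CSVs (one per replicate seed), optional summary
    and snapshots, the resolved config, and the seed list.

    Filenames embed ``scenario_id``.  Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = cfg.game_params()
    written: list[Path] = []

    for seed, records in trajectories.items():
        p = out / f"{scenario_id}_seed{seed}_trajectory.csv"
        write_trajectory(records, p, params, seed)
        written.append(p)
    if summaries:
        p = out / f"{scenario_id}_summary.csv"
        write_summary(summaries, p, cfg.seed)
        written.append(p)
    for (seed, t), state in (snapshots or {}).items():
        p = out / f"{scenario_id}_seed{seed}_t{t:04d}_snapshot.csv"
        write_snapshot(state, p, params)
        written.append(p)

    cfg_path = out / f"{scenario_id}_config.yaml"
    write_config(cfg, cfg_path)
    written.append(cfg_path)
    seeds_path = out / f"{scenario_id}_seeds.txt"
    seeds_path.write_text("".join(f"{s}\n" for s in trajectories))
    written.append(seeds_path)
    return written
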