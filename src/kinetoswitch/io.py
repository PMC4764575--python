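"""File formats, configuration and the end-to-end pipeline driver.

All exchange formats are plain CSV (column units suffixed ``_nm``, ``_s``,
``_deg``) plus a YAML run configuration and a JSON artefact manifest.  The
pipeline glues the stages simulate -> infer -> detect -> profile and is
fully deterministic under a fixed seed: one global seed deterministically
derives per-trajectory and per-chain substreams.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import STATE_LABELS, ModelParams, PairedTrajectory, SIMULATION_PARAMS
from .events import (DirectionalSwitchEvent, event_statistics,
                     events_from_path, MIN_RUN_FRAMES)
from .geometry import MIN_CONSECUTIVE_FRAMES, REST_LENGTH_NM
from .inference import ChainConfig, Priors, run_chain
from .profiles import align_event_windows
from .simulate import simulate_cohort

__all__ = [
    "RunConfig", "Manifest",
    "read_trajectories", "write_trajectories",
    "write_truth_states", "write_events_csv", "read_config", "write_config",
    "run_pipeline",
]

log = logging.getLogger(__name__)

TRAJ_COLUMNS = ["cell_id", "pair_id", "frame", "time_s", "x1_nm", "x2_nm"]
POS_COLUMNS = ["s1_x_nm", "s1_y_nm", "s1_z_nm", "s2_x_nm", "s2_y_nm", "s2_z_nm"]


@dataclass
class RunConfig:
    """Every tunable default of the pipeline, in one place.

    Round-trips losslessly through YAML (read -> write -> read).
    """

    stages: list[str] = field(default_factory=lambda: ["simulate", "infer",
                                                       "detect", "profile"])
    seed: int = 0
    out_dir: str = "runs/out"
    verbosity: str = "INFO"
    # simulation
    params: ModelParams = field(default_factory=lambda: SIMULATION_PARAMS)
    n_traj: int = 10
    n_frames: int = 150
    forced_variant: bool = False
    # inference
    priors: Priors = field(default_factory=Priors)
    chain: ChainConfig = field(default_factory=ChainConfig)
    # detection / filters
    min_run_frames: int = MIN_RUN_FRAMES
    min_track_frames: int = MIN_CONSECUTIVE_FRAMES
    # profiles
    window_s: float = 40.0
    rescale_min_frames: int = 6
    rescale_max_frames: int = 20
    rescale_grid_size: int = 101
    rest_length_nm: float = REST_LENGTH_NM

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["params"] = ModelParams(**d["params"])
        d["priors"] = Priors(**d["priors"])
        d["chain"] = ChainConfig(**d["chain"])
        return cls(**d)


def write_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def read_config(path: str | Path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def write_trajectories(path: str | Path,
                       trajectories: list[PairedTrajectory]) -> None:
    rows = []
    for tr in trajectories:
        df = pd.DataFrame({
            "cell_id": tr.cell_id, "pair_id": tr.pair_id,
            "frame": tr.frames, "time_s": tr.time_s,
            "x1_nm": tr.x1, "x2_nm": tr.x2,
        })
        if tr.pos1 is not None and tr.pos2 is not None:
            for i, col in enumerate(POS_COLUMNS[:3]):
                df[col] = tr.pos1[:, i]
            for i, col in enumerate(POS_COLUMNS[3:]):
                df[col] = tr.pos2[:, i]
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path: str | Path, dt: float = 2.0,
                      ) -> list[PairedTrajectory]:
    """Read paired trajectories from CSV, grouped by (cell_id, pair_id).

    Rows with malformed numeric fields are rejected with their line
    numbers; a missing required column raises naming the column.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    bad_lines = []
    for col in ["frame", "time_s", "x1_nm", "x2_nm"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        newly_bad = coerced.isna() & df[col].notna()
        bad_lines.extend((df.index[newly_bad] + 2).tolist())  # 1-based + header
        df[col] = coerced
    if bad_lines:
        raise ValueError(f"malformed numeric values at line(s) "
                         f"{sorted(set(bad_lines))}")
    has_pos = all(c in df.columns for c in POS_COLUMNS)
    out = []
    for (cell, pair), g in df.groupby(["cell_id", "pair_id"], sort=False):
        g = g.sort_values("frame")
        if len(g) >= 2:
            dts = np.diff(g["time_s"].to_numpy()) / np.maximum(
                np.diff(g["frame"].to_numpy()), 1)
            dt_g = float(np.median(dts))
        else:
            dt_g = dt
        out.append(PairedTrajectory(
            frames=g["frame"].to_numpy(dtype=np.int64),
            x1=g["x1_nm"].to_numpy(dtype=float),
            x2=g["x2_nm"].to_numpy(dtype=float),
            dt=dt_g,
            pos1=g[POS_COLUMNS[:3]].to_numpy(dtype=float) if has_pos else None,
            pos2=g[POS_COLUMNS[3:]].to_numpy(dtype=float) if has_pos else None,
            pair_id=str(pair), cell_id=str(cell)))
    return out


def write_truth_states(path: str | Path, cohort) -> None:
    rows = []
    for traj, truth in cohort:
        for t, s in enumerate(truth.state_path):
            rows.append({"pair_id": traj.pair_id, "frame": t,
                         "state": STATE_LABELS[s]})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_events_csv(path: str | Path,
                     events: list[DirectionalSwitchEvent]) -> None:
    rows = []
    for i, ev in enumerate(events):
        rows.append({
            "pair_id": ev.pair_id, "event_index": i,
            "switch_frame_sister1": ev.switch_frame_sister1,
            "switch_frame_sister2": ev.switch_frame_sister2,
            "event_type": ev.event_type, "lead_sister": ev.lead_sister,
            "completion_time_s": ev.completion_time_s,
            "prior_type": ev.prior_type or "",
            "run_before_start": ev.run_before.start_frame,
            "run_before_end": ev.run_before.end_frame,
            "run_after_start": ev.run_after.start_frame,
            "run_after_end": ev.run_after.end_frame,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class Manifest:
    seed: int
    stages: list[str]
    outputs: list[str] = field(default_factory=list)
    notes: dict = field(default_factory=dict)

    def add(self, path: Path) -> Path:
        self.outputs.append(path.name)
        return path


def run_pipeline(config: RunConfig) -> Manifest:
    """Execute the configured pipeline stages and write all artefacts.

    Returns the manifest (also written as ``manifest.json``); byte-identical
    outputs are produced for identical configs and seeds.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.verbosity)
    manifest = Manifest(seed=config.seed, stages=list(config.stages))

    cohort = None
    if "simulate" in config.stages:
        cohort, truth_summary = simulate_cohort(
            config.params, config.n_traj, config.n_frames,
            forced_variant=config.forced_variant, seed=config.seed)
        write_trajectories(manifest.add(out / "trajectories.csv"),
                           [t for t, _ in cohort])
        write_truth_states(manifest.add(out / "truth_states.csv"), cohort)
        write_events_csv(manifest.add(out / "truth_events.csv"),
                         [ev for _, tr in cohort for ev in tr.event_list])
        manifest.notes["truth"] = dataclasses.asdict(truth_summary)
    elif set(config.stages) & {"infer", "detect", "profile"}:
        cohort = [(t, None) for t in
                  read_trajectories(out / "trajectories.csv")]

    paths_by_pair: dict[str, np.ndarray] = {}
    if "infer" in config.stages:
        seeds = np.random.SeedSequence([config.seed, 1]).generate_state(
            len(cohort))
        excluded = []
        marg_rows = []
        for (traj, _), s in zip(cohort, seeds):
            cfg = dataclasses.replace(config.chain, seed=int(s))
            res = run_chain(traj, config.priors, cfg,
                            enforce_min_length=False)
            if res.excluded:
                excluded.append(traj.pair_id)
                continue
            paths_by_pair[traj.pair_id] = res.summary.modal_path
            m = res.summary.state_marginals
            for t in range(m.shape[0]):
                marg_rows.append({"pair_id": traj.pair_id, "frame": t,
                                  **{f"p_{lbl}": m[t, j] for j, lbl in
                                     enumerate(STATE_LABELS)}})
        pd.DataFrame(marg_rows).to_csv(
            manifest.add(out / "state_marginals.csv"), index=False)
        (manifest.add(out / "exclusions.json")).write_text(
            json.dumps({"excluded_pairs": excluded}, indent=1))
        manifest.notes["n_excluded"] = len(excluded)
    elif set(config.stages) & {"detect", "profile"}:
        # truth-path bypass: detection straight on the generative states
        for traj, truth in cohort:
            if truth is not None:
                paths_by_pair[traj.pair_id] = truth.state_path

    events_by_pair: dict[str, list] = {}
    runs_by_pair: dict[str, list] = {}
    if "detect" in config.stages:
        all_events = []
        for traj, _ in cohort:
            if traj.pair_id not in paths_by_pair:
                continue
            runs, events = events_from_path(
                paths_by_pair[traj.pair_id], dt=traj.dt,
                pair_id=traj.pair_id, min_frames=config.min_run_frames)
            runs_by_pair[traj.pair_id] = runs
            events_by_pair[traj.pair_id] = events
            all_events.extend(events)
        write_events_csv(manifest.add(out / "events.csv"), all_events)
        if all_events:
            stats = event_statistics(
                all_events, [r for rs in runs_by_pair.values() for r in rs])
            (manifest.add(out / "event_stats.json")).write_text(
                json.dumps(dataclasses.asdict(stats), indent=1, default=float))

    if "profile" in config.stages and events_by_pair:
        signals = {t.pair_id: t.x1 - t.x2 for t, _ in cohort
                   if t.pair_id in paths_by_pair}
        all_events = [e for evs in events_by_pair.values() for e in evs]
        rows = []
        for typ in ("LIDS", "TIDS"):
            if not any(e.event_type == typ for e in all_events):
                continue
            prof = align_event_windows(signals, all_events,
                                       window_s=config.window_s,
                                       dt=config.params.dt, event_type=typ)
            for lag, m, s, c in zip(prof.lags_s, prof.mean, prof.sem,
                                    prof.count):
                rows.append({"condition": typ, "lag_s": lag, "mean_nm": m,
                             "sem_nm": s, "n": int(c)})
        pd.DataFrame(rows).to_csv(
            manifest.add(out / "aligned_profiles.csv"), index=False)

    (out / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=1))
    return manifest
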