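"""End-to-end orchestration: config in, report directory out.

A single config (YAML or JSON-equivalent dict) drives the whole
pipeline: obtain trajectories (simulate presets, read CSVs, or track
frame stacks), estimate the dive threshold from the pooled depth
density, classify and flag every trial, and write per-condition
summaries, ethograms, dive events, group statistics and plots.  All
randomness flows from the single config seed, so a report is
reproducible byte-for-byte (PNGs aside) for a fixed config.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import yaml

from . import analyze, classify, io, simulate, stats, track
from .core import BehaviorThresholds, ChamberGeometry, Mode
from .errors import ConfigError, NoMinimumError

__all__ = ["load_config", "run_pipeline"]

_DEFAULTS = {
    "source": "simulate",
    "conditions": ["mel_0.4_noodor"],
    "n_trials": 24,
    "seed": 0,
    "threshold": "auto",
    "threshold_fallback": None,
    "bandwidth": "auto",
    "grid_step": 0.05,
    "escape_seconds": 30.0,
    "inactive_eps_mm": 0.2,
    "inactive_window_s": 120.0,
    "window_s": 60.0,
    "out_dir": "digdive_report",
    "plots": True,
}


def load_config(source: str | Path | dict) -> dict:
    """Normalize a config mapping, filling defaults."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    if raw is None:
        raw = {}
    unknown = set(raw) - set(_DEFAULTS) - {"input_dir", "geometry"}
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = dict(_DEFAULTS)
    cfg.update(raw)
    if cfg["source"] not in ("simulate", "trajectories", "frames"):
        raise ConfigError(f"unknown source {cfg['source']!r}")
    return cfg


def _geometry_from(cfg: dict) -> ChamberGeometry:
    return ChamberGeometry(**cfg.get("geometry", {}))


def _collect_trajectories(cfg: dict, geometry: ChamberGeometry) -> dict[str, list]:
    """Per-condition trajectory lists according to the config source."""
    source = cfg["source"]
    if source == "simulate":
        cohorts = {}
        for cond in cfg["conditions"]:
            params = simulate.preset_params(cond)
            pairs = simulate.simulate_cohort(params, cfg["n_trials"], seed=cfg["seed"], geometry=geometry)
            cohorts[cond] = [traj for traj, _ in pairs]
        return cohorts
    input_dir = Path(cfg.get("input_dir", ""))
    if not input_dir.is_dir():
        raise FileNotFoundError(f"input directory {input_dir} does not exist")
    if source == "trajectories":
        files = sorted(input_dir.glob("*.csv"))
        if not files:
            raise FileNotFoundError(f"no trajectory CSVs in {input_dir}")
        return {input_dir.name: [io.read_trajectory(f, geometry) for f in files]}
    # frames: one multi-page TIFF per trial
    from .render import read_stack

    files = sorted(input_dir.glob("*.tif*"))
    if not files:
        raise FileNotFoundError(f"no TIFF stacks in {input_dir}")
    if geometry.surface_row is None or geometry.center_col is None:
        raise ConfigError("frame tracking requires geometry with surface_row and center_col")
    trajs = []
    for f in files:
        stack = read_stack(f)
        trajs.append(track.track_stack(stack, geometry=geometry, trial_id=f.stem))
    return {input_dir.name: trajs}


def _estimate_threshold(cfg: dict, depths: np.ndarray) -> tuple[BehaviorThresholds, dict]:
    info: dict = {}
    if cfg["threshold"] == "auto":
        dens = classify.depth_pdf(depths, bandwidth=cfg["bandwidth"], grid_step=cfg["grid_step"])
        info["bandwidth_mm"] = dens.bandwidth
        info["mean_depth_mm"] = dens.sample_mean
        try:
            z_div = classify.dive_threshold(dens)
            info["threshold_source"] = "density-minimum"
        except NoMinimumError:
            if cfg["threshold_fallback"] is None:
                raise
            z_div = float(cfg["threshold_fallback"])
            info["threshold_source"] = "fallback"
    else:
        z_div = float(cfg["threshold"])
        info["threshold_source"] = "configured"
    info["z_diving_mm"] = z_div
    return BehaviorThresholds(z_diving=z_div), info


def run_pipeline(config: str | Path | dict) -> Path:
    """Run the full analysis described by ``config``; returns the report dir."""
    cfg = load_config(config)
    geometry = _geometry_from(cfg)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    cohorts = _collect_trajectories(cfg, geometry)
    report: dict = {"conditions": {}}

    tracks_by_cond: dict[str, list] = {}
    for cond, trajs in cohorts.items():
        depths = np.concatenate([t.z[~t.missing] for t in trajs])
        thresholds, thr_info = _estimate_threshold(cfg, depths)
        modetracks = []
        for traj in trajs:
            mt = classify.classify_modes(traj, thresholds, geometry)
            mt = classify.flag_escape(mt, min_out_duration=cfg["escape_seconds"])
            mt = classify.flag_inactive(
                traj, mt, eps_mm=cfg["inactive_eps_mm"], window_s=cfg["inactive_window_s"]
            )
            modetracks.append(mt)
        tracks_by_cond[cond] = modetracks

        summary = analyze.cohort_summary(modetracks, trajs)
        summary.to_csv(out_dir / f"summary_{cond}.csv", index=False, float_format="%.6g")
        io.write_ethogram(modetracks, out_dir / f"ethogram_{cond}.tsv")

        events = [
            ev
            for mt, traj in zip(modetracks, trajs)
            if mt.inactive_from is None
            for ev in analyze.extract_dives(mt, traj)
        ]
        with open(out_dir / f"dives_{cond}.csv", "w") as fh:
            fh.write("trial_id,start_s,end_s,duration_s,max_depth_mm,mean_speed_mm_s\n")
            for ev in events:
                fh.write(
                    f"{ev.trial_id},{ev.start_s:.6g},{ev.end_s:.6g},{ev.duration_s:.6g},"
                    f"{ev.max_depth_mm:.6g},{ev.mean_speed_mm_s:.6g}\n"
                )

        report["conditions"][cond] = {
            "threshold": thr_info,
            "aggregates": analyze.cohort_aggregates(summary),
            "n_excluded_inactive": sum(mt.inactive_from is not None for mt in modetracks),
        }

        if cfg["plots"]:
            _plot_condition(out_dir, cond, depths, cfg, modetracks)

    conds = list(cohorts)
    if len(conds) >= 2:
        report["comparisons"] = _compare_conditions(tracks_by_cond, list(cohorts.items()))
    with open(out_dir / "stats.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return out_dir


def _compare_conditions(tracks_by_cond: dict[str, list], cohorts: list) -> dict:
    """Pairwise and multi-group comparisons of the diving time fraction."""
    pct = {}
    for cond, mts in tracks_by_cond.items():
        vals = []
        for mt in mts:
            if mt.inactive_from is not None:
                continue
            vals.append(analyze.mode_time_fractions(mt)[Mode.DIVING])
        pct[cond] = np.array(vals)
    out: dict = {"metric": "pct_diving"}
    conds = list(pct)
    pairs = {}
    for i in range(len(conds)):
        for j in range(i + 1, len(conds)):
            res = stats.rank_sum_test(pct[conds[i]], pct[conds[j]])
            pairs[f"{conds[i]} vs {conds[j]}"] = {
                "test": res.test_name,
                "statistic": res.statistic,
                "p_value": res.p_value,
            }
    out["pairwise"] = pairs
    if len(conds) > 2:
        kp = stats.kruskal_posthoc([pct[c] for c in conds])
        out["kruskal"] = {
            "p_value": kp.kruskal_p,
            "letters": dict(zip(conds, kp.letters)),
        }
    return out


def _plot_condition(out_dir: Path, cond: str, depths: np.ndarray, cfg: dict, modetracks) -> None:
    dens = classify.depth_pdf(depths, bandwidth=cfg["bandwidth"], grid_step=cfg["grid_step"])
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(dens.density, dens.grid, color="crimson")
    ax1.axhline(0.0, color="k", lw=0.8, ls="--")
    ax1.set_xlabel("density (1/mm)")
    ax1.set_ylabel("depth z (mm)")
    ax1.set_title(f"{cond}: depth PDF")

    order = np.argsort([mt.total_time_in(Mode.DIVING) for mt in modetracks])
    codes = {"S": 0, "G": 1, "V": 2, "E": 3, "X": 4}
    raster = np.array([[codes[c] for c in modetracks[i].labels] for i in order])
    ax2.imshow(raster, aspect="auto", interpolation="nearest", cmap="viridis", vmin=0, vmax=4)
    ax2.set_xlabel("time (frames)")
    ax2.set_ylabel("trial (sorted by total dive time)")
    ax2.set_title("ethogram")
    fig.tight_layout()
    fig.savefig(out_dir / f"overview_{cond}.png", dpi=110)
    plt.close(fig)
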