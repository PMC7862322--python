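"""Closed-loop experiment orchestration.

Wires the plant, monitor, controller, stimulation, and fluidics modules
into the two headline experiments:

* ``FEEDBACK_LD`` — 13 h feedback regulation of lipid-droplet size at a
  1 h imaging cadence: the plant evolves under the active stimulant, each
  rendered frame is reduced to the white-pixel index, and the bang-bang
  controller decides the stimulant for the next interval.
* ``SM_TOTAL`` — 24 h total-system run on skeletal muscle: electrical
  stimulation from 12 h, automated sampling at programmed times through
  the fluidic chain, contraction-imaging rounds during stimulation, and
  the stimulated-vs-control lactate excess read from the aliquots.

Two auxiliary modes reuse the same plumbing: ``MONITOR_ONLY`` renders and
indexes an open-loop schedule, ``SAMPLING_ONLY`` runs just the metabolite
plant and sampler.

A run is fully determined by (config, seed); the record's digest hashes
every emitted table so re-runs can be checked bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import control, fluidics, monitor, plant, stim
from .contraction import ContractionMovieSpec, generate_contraction_movie, trace_displacement
from .stimulant import Stimulant

__all__ = [
    "RunConfig",
    "RunRecord",
    "run_experiment",
    "run_feedback_experiment",
    "run_sm_total_experiment",
    "load_config",
]

EXPERIMENTS = ("FEEDBACK_LD", "SM_TOTAL", "MONITOR_ONLY", "SAMPLING_ONLY")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Declarative description of one simulated experiment."""

    experiment: str = "FEEDBACK_LD"
    duration: float = 13.0  # hours
    imaging_interval: float = 1.0  # hours
    seed: int = 0
    # plant (FEEDBACK_LD / MONITOR_ONLY)
    n_droplets: int = 150
    frame_shape: tuple[int, int] = (240, 320)
    growth_rate: float = 0.4
    shrink_rate: float = 0.6
    drift_velocity: float = 0.0
    jump_rate: float = 0.0
    noise_sd: float = 0.0
    # controller
    threshold: float = 0.3
    initial_stimulant: str = "insulin"
    reference_mode: str = "on_switch"
    # fluidics / metabolites (SM_TOTAL / SAMPLING_ONLY)
    sampling_times: tuple[float, ...] = (0.0, 3.0, 6.0, 12.0, 18.0, 24.0)
    stim_window: tuple[float, float] = (12.0, 24.0)
    total_system_excess: float = 0.07  # lactate excess pinned at full stimulation
    sensor_noise_sd: float = 0.0
    # contraction imaging rounds (SM_TOTAL)
    capture_hours: tuple[float, ...] = (12.0, 18.0, 24.0)
    capture_seconds: float = 5.0
    capture_fps: float = 5.0
    movie_shape: tuple[int, int] = (96, 96)
    peak_displacement: float = 3.0
    # stimulation waveform (recorded for provenance in SM_TOTAL)
    stimulation: stim.PulseTrainSpec = dataclasses.field(default_factory=stim.PulseTrainSpec)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"experiment must be one of {EXPERIMENTS}")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.imaging_interval <= 0:
            raise ValueError("imaging_interval must be > 0")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["stimulation"] = dataclasses.asdict(self.stimulation)
        return d


@dataclasses.dataclass
class RunRecord:
    """All artifacts of one run, plus provenance."""

    config: RunConfig
    index_trace: pd.DataFrame
    actions: pd.DataFrame
    events: pd.DataFrame
    aliquots: pd.DataFrame
    displacement: pd.DataFrame
    summary: dict[str, Any]

    def digest(self) -> str:
        """SHA-256 over the canonical CSV text of every table."""
        h = hashlib.sha256()
        for df in (self.index_trace, self.actions, self.events, self.aliquots, self.displacement):
            h.update(df.to_csv(index=False, float_format="%.10g").encode())
        return h.hexdigest()

    def to_dir(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh, sort_keys=False)
        self.index_trace.to_csv(out / "index.csv", index=False)
        self.actions.to_csv(out / "actions.csv", index=False)
        self.events.to_csv(out / "events.csv", index=False)
        self.aliquots.to_csv(out / "aliquots.csv", index=False)
        self.displacement.to_csv(out / "displacement.csv", index=False)
        summary = dict(self.summary, digest=self.digest())
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        return out


def _empty(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame(columns=columns)


def run_feedback_experiment(cfg: RunConfig, save_frames: str | Path | None = None) -> RunRecord:
    """Closed-loop LD size regulation (or open-loop if MONITOR_ONLY)."""
    if cfg.experiment not in ("FEEDBACK_LD", "MONITOR_ONLY"):
        raise ValueError(f"config experiment is {cfg.experiment}, not FEEDBACK_LD/MONITOR_ONLY")
    closed_loop = cfg.experiment == "FEEDBACK_LD"
    state = plant.make_plant(
        n_droplets=cfg.n_droplets,
        frame_shape=cfg.frame_shape,
        seed=cfg.seed,
        active_stimulant=Stimulant.parse(cfg.initial_stimulant),
        growth_rate=cfg.growth_rate,
        shrink_rate=cfg.shrink_rate,
        drift_velocity=cfg.drift_velocity,
        jump_rate=cfg.jump_rate,
        noise_sd=cfg.noise_sd,
    )
    n_steps = int(round(cfg.duration / cfg.imaging_interval))
    frames, index_rows, action_rows = [], [], []

    frame = plant.render_frame(state)
    frames.append(frame)
    idx = monitor.compute_index(frame, frame_id=0, time=0.0)
    ctrl = control.initialize(
        idx,
        cfg.initial_stimulant,
        threshold=cfg.threshold,
        reference_mode=cfg.reference_mode,
    )
    action = ctrl.active_stimulant
    index_rows.append({"frame_id": 0, "time_h": 0.0, "index_percent": idx.value})
    action_rows.append({"frame_id": 0, "time_h": 0.0, "action": action.value})

    for k in range(1, n_steps + 1):
        t = k * cfg.imaging_interval
        state = plant.step_plant(state, cfg.imaging_interval, action)
        frame = plant.render_frame(state)
        frames.append(frame)
        idx = monitor.compute_index(frame, frame_id=k, time=t)
        if closed_loop:
            action, ctrl = control.step(ctrl, idx)
        index_rows.append({"frame_id": k, "time_h": t, "index_percent": idx.value})
        action_rows.append({"frame_id": k, "time_h": t, "action": action.value})

    if save_frames is not None:
        plant.write_frames(frames, save_frames)

    events = control.events_table(ctrl)
    summary = {
        "experiment": cfg.experiment,
        "seed": cfg.seed,
        "n_frames": len(frames),
        "n_switches": int(len(events)),
        "final_index_percent": float(index_rows[-1]["index_percent"]),
        "reference_index_percent": float(ctrl.reference_index),
    }
    return RunRecord(
        config=cfg,
        index_trace=pd.DataFrame(index_rows),
        actions=pd.DataFrame(action_rows),
        events=events,
        aliquots=_empty(["time_h", "volume_ul", "lactate_mM", "glucose_mM", "container_id"]),
        displacement=_empty(["round_h", "frame_pair", "time_s", "mean_px"]),
        summary=summary,
    )


def run_sm_total_experiment(cfg: RunConfig) -> RunRecord:
    """24 h total-system run: stimulation, sampling, contraction imaging.

    The lactate excess law is rescaled so that a full stimulation window
    in this experiment yields ``total_system_excess`` (7% by default) —
    the documented per-experiment calibration reconciling the total-system
    run with the dedicated stimulation experiment.
    """
    if cfg.experiment != "SM_TOTAL":
        raise ValueError(f"config experiment is {cfg.experiment}, not SM_TOTAL")
    start, end = cfg.stim_window
    end = min(end, cfg.duration)
    base = fluidics.MetabolitePlant(stim_window=(start, end))
    full_window = max(end - start, 1e-9)
    scale = cfg.total_system_excess / base.excess(full_window)
    mplant = dataclasses.replace(base, excess_scale=scale)

    seedseq = np.random.SeedSequence(cfg.seed)
    sensor_seeds = seedseq.generate_state(2 * len(cfg.sampling_times)).tolist()

    stim_arm = fluidics.SamplerState(schedule=tuple(cfg.sampling_times))
    ctrl_arm = fluidics.SamplerState(schedule=tuple(cfg.sampling_times))
    rows = []
    for i, t in enumerate(cfg.sampling_times):
        if t > cfg.duration:
            break
        c_stim = fluidics.metabolite_concentrations(mplant, t, stimulated=True)
        c_ctrl = fluidics.metabolite_concentrations(mplant, t, stimulated=False)
        stim_arm = fluidics.run_sampling_cycle(stim_arm, t, c_stim)
        ctrl_arm = fluidics.run_sampling_cycle(ctrl_arm, t, c_ctrl)
        lac_s, glu_s = fluidics.biosensor_read(
            stim_arm.containers[-1], cfg.sensor_noise_sd, seed=int(sensor_seeds[2 * i])
        )
        lac_c, glu_c = fluidics.biosensor_read(
            ctrl_arm.containers[-1], cfg.sensor_noise_sd, seed=int(sensor_seeds[2 * i + 1])
        )
        rows.append(
            {
                "time_h": t,
                "lactate_stim_mM": lac_s,
                "lactate_ctrl_mM": lac_c,
                "glucose_stim_mM": glu_s,
                "glucose_ctrl_mM": glu_c,
                "excess_percent": 100.0 * (lac_s - lac_c) / lac_c if lac_c > 0 else 0.0,
            }
        )
    metabolites = pd.DataFrame(rows)

    disp_rows = []
    movie_seeds = np.random.SeedSequence([cfg.seed, 13]).generate_state(
        len(cfg.capture_hours)
    )
    for j, hour in enumerate(cfg.capture_hours):
        if not (start <= hour <= end):
            continue
        spec = ContractionMovieSpec(
            n_frames=int(round(cfg.capture_seconds * cfg.capture_fps)),
            frame_rate=cfg.capture_fps,
            peak_displacement=cfg.peak_displacement,
            frame_shape=cfg.movie_shape,
            seed=int(movie_seeds[j]),
        )
        movie, _gt = generate_contraction_movie(spec)
        trace = trace_displacement(movie, spec.frame_rate)
        for pair, (ts, mag) in enumerate(zip(trace.times, trace.mean_magnitude)):
            disp_rows.append(
                {"round_h": hour, "frame_pair": pair, "time_s": float(ts), "mean_px": float(mag)}
            )
    displacement = pd.DataFrame(
        disp_rows, columns=["round_h", "frame_pair", "time_s", "mean_px"]
    )

    final = metabolites.iloc[-1] if len(metabolites) else None
    summary = {
        "experiment": cfg.experiment,
        "seed": cfg.seed,
        "n_aliquots_per_arm": int(len(stim_arm.containers)),
        "excess_percent_final": float(final["excess_percent"]) if final is not None else None,
        "excess_scale": float(scale),
        "stimulation_pulses_per_burst": stim.PulseTrainSpec().pulses_per_burst,
        "peak_displacement_px": (
            float(displacement["mean_px"].max()) if len(displacement) else None
        ),
    }
    return RunRecord(
        config=cfg,
        index_trace=metabolites,  # the monitored trace of this experiment
        actions=_empty(["frame_id", "time_h", "action"]),
        events=_empty(["time_h", "from", "to", "index_percent"]),
        aliquots=fluidics.aliquot_table(stim_arm),
        displacement=displacement,
        summary=summary,
    )


def run_experiment(cfg: RunConfig, save_frames: str | Path | None = None) -> RunRecord:
    """Dispatch on ``cfg.experiment``."""
    if cfg.experiment in ("FEEDBACK_LD", "MONITOR_ONLY"):
        return run_feedback_experiment(cfg, save_frames=save_frames)
    if cfg.experiment == "SM_TOTAL":
        return run_sm_total_experiment(cfg)
    # SAMPLING_ONLY: metabolite plant + sampler, no imaging
    sub = dataclasses.replace(cfg, experiment="SM_TOTAL", capture_hours=())
    rec = run_sm_total_experiment(sub)
    rec.summary["experiment"] = "SAMPLING_ONLY"
    return rec


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file.

    Top-level keys map to RunConfig fields; nested blocks ``controller:``,
    ``sampling:`` and ``stimulation:`` are accepted as in the run
    artifacts.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict[str, Any] = {}
    controller = raw.pop("controller", {})
    if "threshold_pp" in controller:
        kwargs["threshold"] = float(controller["threshold_pp"])
    if "initial" in controller:
        kwargs["initial_stimulant"] = str(controller["initial"])
    if "reference_mode" in controller:
        kwargs["reference_mode"] = str(controller["reference_mode"])
    sampling = raw.pop("sampling", {})
    if "times_h" in sampling:
        kwargs["sampling_times"] = tuple(float(t) for t in sampling["times_h"])
    stimulation = raw.pop("stimulation", None)
    if stimulation:
        kwargs["stimulation"] = stim.PulseTrainSpec(**stimulation)
    fields = {f.name for f in dataclasses.fields(RunConfig)}
    for key, value in raw.items():
        if key not in fields:
            raise ValueError(f"unknown config key {key!r}")
        if key in ("frame_shape", "movie_shape", "stim_window", "sampling_times", "capture_hours"):
            value = tuple(value)
        kwargs[key] = value
    return RunConfig(**kwargs)
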