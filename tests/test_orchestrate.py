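"""End-to-end experiment orchestration, config handling, and the CLI."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from ochip_loop.cli import main
from ochip_loop.orchestrate import (
    RunConfig,
    load_config,
    run_experiment,
    run_feedback_experiment,
    run_sm_total_experiment,
)


@pytest.fixture(scope="module")
def default_feedback_record():
    return run_feedback_experiment(RunConfig(seed=5))


class TestFeedbackExperiment:
    def test_index_confined_to_reference_band(self, default_feedback_record):
        """Closed loop holds every post-initialization index within
        reference +- (threshold + one-step plant excursion)."""
        rec = default_feedback_record
        values = rec.index_trace["index_percent"].to_numpy()
        excursion = np.abs(np.diff(values)).max()
        threshold = rec.config.threshold
        # reconstruct the controller reference ahead of each frame
        ref = values[0]
        for v, t in zip(values[1:], rec.index_trace["time_h"][1:]):
            assert abs(v - ref) <= threshold + excursion + 1e-9
            if abs(v - ref) > threshold:
                ref = v

    def test_switches_occur_in_both_directions(self, default_feedback_record):
        events = default_feedback_record.events
        assert ((events["from"] == "insulin") & (events["to"] == "adrenaline")).any()
        assert ((events["from"] == "adrenaline") & (events["to"] == "insulin")).any()

    def test_unreachable_threshold_never_switches(self):
        rec = run_feedback_experiment(RunConfig(threshold=100.0, duration=5.0))
        assert len(rec.events) == 0
        assert set(rec.actions["action"]) == {"insulin"}

    def test_bit_identical_rerun(self):
        a = run_feedback_experiment(RunConfig(seed=3, duration=5.0))
        b = run_feedback_experiment(RunConfig(seed=3, duration=5.0))
        assert a.digest() == b.digest()
        c = run_feedback_experiment(RunConfig(seed=4, duration=5.0))
        assert a.digest() != c.digest()

    def test_drift_disturbance_can_oppose_the_stimulant(self):
        """With cluster drift and jumps, the index sometimes falls while
        insulin is being supplied (clusters leaving the frame)."""
        rec = run_feedback_experiment(
            RunConfig(seed=11, drift_velocity=12.0, jump_rate=0.6, duration=13.0)
        )
        df = rec.index_trace.merge(rec.actions, on=["frame_id", "time_h"])
        deltas = df["index_percent"].diff()[1:]
        supplied = df["action"][:-1].to_numpy()  # stimulant active during each interval
        opposed = ((supplied == "insulin") & (deltas.to_numpy() < 0)) | (
            (supplied == "adrenaline") & (deltas.to_numpy() > 0)
        )
        assert opposed.any()

    def test_wrong_experiment_kind_rejected(self):
        with pytest.raises(ValueError, match="FEEDBACK_LD"):
            run_feedback_experiment(RunConfig(experiment="SM_TOTAL"))
        with pytest.raises(ValueError, match="SM_TOTAL"):
            run_sm_total_experiment(RunConfig(experiment="FEEDBACK_LD"))


@pytest.fixture(scope="module")
def record():
    return run_sm_total_experiment(
        RunConfig(experiment="SM_TOTAL", duration=24.0, seed=2)
    )


class TestSmTotalExperiment:
    def test_no_excess_at_stimulation_onset(self, record):
        row = record.index_trace.set_index("time_h").loc[12.0]
        assert row["excess_percent"] == pytest.approx(0.0, abs=1e-9)

    def test_seven_percent_excess_at_24h(self, record):
        row = record.index_trace.set_index("time_h").loc[24.0]
        assert row["excess_percent"] == pytest.approx(7.0, abs=1e-6)

    def test_glucose_agrees_between_arms(self, record):
        df = record.index_trace
        np.testing.assert_allclose(df["glucose_stim_mM"], df["glucose_ctrl_mM"])

    def test_aliquots_follow_schedule(self, record):
        assert list(record.aliquots["time_h"]) == [0.0, 3.0, 6.0, 12.0, 18.0, 24.0]
        assert np.allclose(record.aliquots["volume_ul"], 40.0, atol=0.05)

    def test_contraction_rounds_traced(self, record):
        assert set(record.displacement["round_h"]) == {12.0, 18.0, 24.0}
        assert record.summary["peak_displacement_px"] == pytest.approx(3.0, rel=0.2)

    def test_deterministic_rerun(self):
        cfg = RunConfig(experiment="SM_TOTAL", seed=8, duration=24.0,
                        capture_hours=(12.0,))
        assert run_sm_total_experiment(cfg).digest() == run_sm_total_experiment(cfg).digest()


class TestRunArtifacts:
    def test_run_directory_schema(self, tmp_path, default_feedback_record):
        out = default_feedback_record.to_dir(tmp_path / "run")
        assert yaml.safe_load((out / "config.yaml").read_text())["experiment"] == "FEEDBACK_LD"
        index = pd.read_csv(out / "index.csv")
        assert list(index.columns) == ["frame_id", "time_h", "index_percent"]
        events = pd.read_csv(out / "events.csv")
        assert list(events.columns) == ["time_h", "from", "to", "index_percent"]
        actions = pd.read_csv(out / "actions.csv")
        assert list(actions.columns) == ["frame_id", "time_h", "action"]
        summary = yaml.safe_load((out / "summary.json").read_text())
        assert summary["digest"] == default_feedback_record.digest()

    def test_config_validation(self):
        with pytest.raises(ValueError, match="experiment"):
            RunConfig(experiment="PCR")
        with pytest.raises(ValueError, match="duration"):
            RunConfig(duration=0.0)

    def test_load_config_roundtrip(self, tmp_path):
        cfg_file = tmp_path / "cfg.yaml"
        cfg_file.write_text(
            "experiment: FEEDBACK_LD\n"
            "duration: 6.0\n"
            "seed: 12\n"
            "controller: {threshold_pp: 0.5, initial: adrenaline, reference_mode: on_switch}\n"
            "sampling: {times_h: [0, 6]}\n"
            "stimulation: {frequency: 20.0, pulse_width: 0.004}\n"
        )
        cfg = load_config(cfg_file)
        assert cfg.duration == 6.0
        assert cfg.threshold == 0.5
        assert cfg.initial_stimulant == "adrenaline"
        assert cfg.sampling_times == (0.0, 6.0)
        assert cfg.stimulation.frequency == 20.0
        with pytest.raises(ValueError, match="unknown config key"):
            load_config_with_bad_key(tmp_path)

    def test_sampling_only_mode(self):
        rec = run_experiment(RunConfig(experiment="SAMPLING_ONLY", duration=24.0))
        assert rec.summary["experiment"] == "SAMPLING_ONLY"
        assert len(rec.aliquots) == 6
        assert len(rec.displacement) == 0


def load_config_with_bad_key(tmp_path):
    bad = tmp_path / "bad.yaml"
    bad.write_text("experiment: FEEDBACK_LD\nvoltage: 12\n")
    from ochip_loop.orchestrate import load_config as lc

    return lc(bad)


class TestCli:
    def test_waveform_preview(self):
        result = CliRunner().invoke(main, ["waveform", "--preview"])
        assert result.exit_code == 0
        assert "40 pulses" in result.output

    def test_monitor_and_control_roundtrip(self, tmp_path):
        from ochip_loop.plant import make_plant, render_frame, step_plant, write_frames

        state = make_plant(n_droplets=40, frame_shape=(128, 128), seed=6)
        frames = [render_frame(state)]
        for _ in range(3):
            state = step_plant(state, 2.0, "insulin")
            frames.append(render_frame(state))
        frames_dir = tmp_path / "frames"
        write_frames(frames, frames_dir)

        index_csv = tmp_path / "index.csv"
        result = CliRunner().invoke(
            main, ["monitor", "--in", str(frames_dir), "--out", str(index_csv)]
        )
        assert result.exit_code == 0, result.output
        trace = pd.read_csv(index_csv)
        assert len(trace) == 4

        out_csv = tmp_path / "actions.csv"
        result = CliRunner().invoke(
            main, ["control", "--replay", str(index_csv), "--out", str(out_csv)]
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "actions_events.csv").exists()

    def test_simulate_writes_run_directory(self, tmp_path):
        out_dir = tmp_path / "run"
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("experiment: FEEDBACK_LD\nduration: 3.0\nn_droplets: 40\n"
                       "frame_shape: [128, 128]\n")
        result = CliRunner().invoke(
            main, ["simulate", "--config", str(cfg), "--seed", "1", "--out", str(out_dir)]
        )
        assert result.exit_code == 0, result.output
        assert (out_dir / "summary.json").exists()
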