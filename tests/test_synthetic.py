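"""Synthetic experiment generator: design, kinematics, noise, ground truth."""

import json

import numpy as np
import pandas as pd
import pytest

from activegaze.errors import InvalidInputError
from activegaze.geometry import directions_angle_deg, path_length
from activegaze.pipeline import analyze_sim
from activegaze.simulate import (
    BehaviorParams,
    NoiseParams,
    generate_design,
    simulate_experiment,
    simulate_trial,
)


class TestGenerateDesign:
    def test_full_experiment_row_count(self):
        design = generate_design(47, 18, seed=0)
        assert len(design) == 846

    def test_complexity_balanced_within_subject(self):
        design = generate_design(5, 18, seed=1)
        counts = design.groupby("subject_id")["complexity"].value_counts()
        assert (counts == 6).all()

    def test_deterministic_given_seed(self):
        a = generate_design(4, 18, seed=9)
        b = generate_design(4, 18, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_indivisible_trials_rejected(self):
        with pytest.raises(InvalidInputError):
            generate_design(5, 17, seed=0)


class TestSimulateTrialZeroNoise:
    def test_detector_recovers_schedule_exactly(self, small_design, quiet_params):
        sim = simulate_trial(small_design.iloc[0].to_dict(), quiet_params, seed=21)
        _, fixes, m = analyze_sim(sim, min_step=0.0)
        truth = sim.truth
        assert len(fixes) == len(truth.fixations)
        assert [f.label for f in fixes] == truth.labels()
        for det, sched in zip(fixes, truth.fixations):
            assert det.t_start == pytest.approx(sched.t_start, abs=1e-9)
            assert det.t_end == pytest.approx(sched.t_end, abs=1e-9)
        assert m.response_time == pytest.approx(
            truth.answer_time_s - truth.first_fixation_t, abs=1e-9
        )
        assert m.head_path == pytest.approx(truth.head_path_m, abs=1e-6)

    def test_head_stays_inside_arena(self, small_design, quiet_params):
        for i in range(4):
            sim = simulate_trial(small_design.iloc[i].to_dict(), quiet_params, seed=50 + i)
            pos = sim.head.position
            arena = quiet_params.arena
            assert np.all(pos[:, 0] >= 0) and np.all(pos[:, 0] <= arena.width_x)
            assert np.all(pos[:, 1] >= 0) and np.all(pos[:, 1] <= arena.depth_y)

    def test_ground_truth_intervals_disjoint_and_alternating(self, small_design, quiet_params):
        sim = simulate_trial(small_design.iloc[2].to_dict(), quiet_params, seed=31)
        fixes = sim.truth.fixations
        for a, b in zip(fixes, fixes[1:]):
            assert a.t_end < b.t_start
        # object labels alternate between groups by construction
        obj_labels = [f.label for f in fixes if f.label != "environment"]
        runs = []
        for lab in obj_labels:
            if not runs or runs[-1][0] != lab:
                runs.append([lab, 1])
            else:
                runs[-1][1] += 1
        assert [r[1] for r in runs] == sim.truth.group_sizes

    def test_streams_carry_nominal_rates(self, small_design, quiet_params):
        sim = simulate_trial(small_design.iloc[1].to_dict(), quiet_params, seed=22)
        np.testing.assert_allclose(np.diff(sim.head.t), 1 / 120, atol=1e-12)
        np.testing.assert_allclose(np.diff(sim.gaze.t), 0.02, atol=1e-12)


class TestNoiseModel:
    def test_mean_gaze_error_calibrated(self, small_design):
        """Mean angular error over a long stretch approximates the 1.42 deg
        tracker accuracy."""
        errs = []
        for i in range(8):
            row = small_design.iloc[i].to_dict()
            noisy = simulate_trial(row, BehaviorParams(), seed=800 + i)
            quiet = simulate_trial(
                row, BehaviorParams(noise=NoiseParams(enabled=False)), seed=800 + i
            )
            assert len(noisy.gaze) == len(quiet.gaze)
            errs.append(
                directions_angle_deg(noisy.gaze.direction, quiet.gaze.direction).mean()
            )
        assert np.mean(errs) == pytest.approx(1.42, abs=0.1)

    def test_head_noise_rmse_calibrated(self, small_design):
        row = small_design.iloc[0].to_dict()
        noisy = simulate_trial(row, BehaviorParams(), seed=808)
        quiet = simulate_trial(
            row, BehaviorParams(noise=NoiseParams(enabled=False)), seed=808
        )
        d = noisy.head.position - quiet.head.position
        rmse = np.sqrt(np.mean(np.sum(d**2, axis=1)))
        assert rmse == pytest.approx(0.0002, rel=0.1)

    def test_noisy_head_path_agrees_with_truth(self, small_design, noisy_params):
        """Anchored 2 mm integration of the noisy stream stays within 5% of
        the scheduled walking distance."""
        for i in range(5):
            sim = simulate_trial(small_design.iloc[i].to_dict(), noisy_params, seed=880 + i)
            measured = path_length(sim.head.position, 0.002)
            assert measured == pytest.approx(sim.truth.head_path_m, rel=0.05)


class TestSimulateExperiment:
    def test_tree_layout_and_determinism(self, tmp_path):
        design = generate_design(2, 18, seed=3)
        out1 = simulate_experiment(design, seed=3, outdir=tmp_path / "a")
        assert len(list(p for p in out1.iterdir() if p.is_dir())) == 36
        with open(out1 / "manifest.json") as fh:
            manifest = json.load(fh)
        assert manifest["n_trials"] == 36
        out2 = simulate_experiment(design, seed=3, outdir=tmp_path / "b")
        name = manifest["trials"][0]["dir"]
        for fname in ["head.csv", "gaze.csv", "trial.json", "truth.json", "objects.json"]:
            assert (out1 / name / fname).read_bytes() == (out2 / name / fname).read_bytes()

    def test_answer_accuracy_follows_configured_probability(self):
        """Across many trials the share of correct answers approaches the
        configured per-complexity probability."""
        design = generate_design(12, 18, seed=6)
        # short itineraries: this only exercises the answer model
        params = BehaviorParams(
            noise=NoiseParams(enabled=False),
            mean_fixations={"C_e": 10.0, "C_m": 10.0, "C_h": 10.0},
        )
        correct = {c: [] for c in ("C_e", "C_m", "C_h")}
        for i, row in enumerate(design.to_dict("records")):
            sim = simulate_trial(row, params, seed=4000 + i)
            correct[row["complexity"]].append(sim.truth.correct)
        for c, vals in correct.items():
            assert np.mean(vals) == pytest.approx(params.accuracy[c], abs=0.08)
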