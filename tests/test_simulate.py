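"""Generator contracts: trajectories, samples, videos, compositions, cohorts."""

import numpy as np
import pandas as pd
import pytest

from cvmbarrier.simulate import (
    CohortConfig,
    OpticsConfig,
    PopulationSpec,
    render_video,
    simulate_cohort,
    simulate_composition,
    simulate_composition_table,
    simulate_sample,
    simulate_trajectory,
)
from cvmbarrier.simulate.cohort import DEFAULT_TRANSITIONS
from cvmbarrier.msd import time_averaged_msd


class TestSimulateTrajectory:
    def test_zero_diffusivity_stays_at_origin(self):
        traj = simulate_trajectory(0.0, 1.0, 50, 1 / 15, seed=0)
        assert np.all(traj.positions == 0.0)

    @pytest.mark.parametrize("alpha", [1.0, 0.5])
    def test_ensemble_msd_matches_closed_form(self, alpha):
        # E[MSD(tau)] = 4 D tau^alpha; check at tau = 1 s within 3 SE
        D, dt, n = 0.1, 1 / 15, 300
        msds = np.array([
            time_averaged_msd(
                simulate_trajectory(D, alpha, n, dt, seed=s), 1.0).msd
            for s in range(400)])
        expected = 4 * D * 1.0 ** alpha
        se = msds.std(ddof=1) / np.sqrt(len(msds))
        assert abs(msds.mean() - expected) < 3 * se

    def test_same_seed_bitwise_identical(self):
        a = simulate_trajectory(0.2, 0.7, 100, 1 / 15, seed=42)
        b = simulate_trajectory(0.2, 0.7, 100, 1 / 15, seed=42)
        np.testing.assert_array_equal(a.positions, b.positions)

    @pytest.mark.parametrize("kwargs,match", [
        (dict(diffusivity=-1.0), "diffusivity"),
        (dict(diffusivity=np.nan), "diffusivity"),
        (dict(anomalous_exponent=0.0), "anomalous_exponent"),
        (dict(anomalous_exponent=1.5), "anomalous_exponent"),
        (dict(n_frames=1), "n_frames"),
        (dict(dt=0.0), "dt"),
    ])
    def test_invalid_inputs_name_the_parameter(self, kwargs, match):
        defaults = dict(diffusivity=0.1, anomalous_exponent=1.0,
                        n_frames=10, dt=1 / 15)
        defaults.update(kwargs)
        with pytest.raises(ValueError, match=match):
            simulate_trajectory(**defaults)


class TestSimulateSample:
    def test_single_population_all_labelled(self):
        ts = simulate_sample([PopulationSpec("mobile", 1.0, 0.5)], 20, seed=0)
        assert ts.labels == ["mobile"] * 20

    def test_quota_assignment_exact_counts(self):
        pops = [PopulationSpec("trapped", 0.7, 1e-4),
                PopulationSpec("mobile", 0.3, 0.5)]
        ts = simulate_sample(pops, 500, seed=1)
        assert ts.labels.count("trapped") == 350
        assert ts.labels.count("mobile") == 150

    def test_empty_sample_is_valid(self):
        ts = simulate_sample([PopulationSpec("mobile", 1.0, 0.5)], 0, seed=0)
        assert len(ts) == 0

    def test_fractions_must_sum_to_one(self):
        pops = [PopulationSpec("a", 0.5, 0.1), PopulationSpec("b", 0.4, 0.1)]
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_sample(pops, 10, seed=0)


class TestRenderVideo:
    def test_stationary_particle_argmax_at_truth(self, small_optics):
        from cvmbarrier.simulate.trajectories import Trajectory, TrajectorySet
        x_px, y_px = 60, 40
        n = small_optics.n_frames
        traj = Trajectory(0, np.arange(n),
                          np.tile([x_px * 0.025, y_px * 0.025], (n, 1)),
                          small_optics.dt)
        stack = render_video(TrajectorySet([traj]),
                             OpticsConfig(image_shape=(128, 128),
                                          duration=2.0, photon_scale=5000,
                                          background=0.0),
                             seed=0, shot_noise=False)
        for frame in stack:
            r, c = np.unravel_index(np.argmax(frame), frame.shape)
            assert (r, c) == (y_px, x_px)

    def test_empty_set_gives_background_noise(self, small_optics):
        from cvmbarrier.simulate.trajectories import TrajectorySet
        stack = render_video(TrajectorySet([]), small_optics, seed=0)
        assert stack.shape == (small_optics.n_frames, 128, 128)
        assert abs(stack.mean() - small_optics.background) < 2.0

    def test_out_of_field_rejected_by_default(self, small_optics):
        from cvmbarrier.simulate.trajectories import Trajectory, TrajectorySet
        n = small_optics.n_frames
        traj = Trajectory(0, np.arange(n), np.tile([50.0, 1.0], (n, 1)),
                          small_optics.dt)
        with pytest.raises(ValueError, match="field of view"):
            render_video(TrajectorySet([traj]), small_optics, seed=0)
        # clip mode renders anyway
        stack = render_video(TrajectorySet([traj]), small_optics, seed=0,
                             out_of_field="clip")
        assert stack.shape[0] == n

    def test_same_seed_identical_stack(self, small_optics):
        from cvmbarrier.simulate.trajectories import TrajectorySet
        ts = simulate_sample([PopulationSpec("m", 1.0, 0.005)], 3,
                             small_optics, seed=5, margin_um=1.0)
        a = render_video(ts, small_optics, seed=9)
        b = render_video(ts, small_optics, seed=9)
        np.testing.assert_array_equal(a, b)


class TestSimulateComposition:
    def test_simplex_normalization(self):
        for lbl in ("I", "II", "III", "IV", "V"):
            v = simulate_composition(lbl, seed=3)
            assert np.all(v.to_numpy() >= 0)
            assert abs(v.sum() - 1.0) < 1e-9

    def test_archetype_dominates_cst_i(self):
        r = np.random.default_rng(11)
        hits = sum(simulate_composition("I", seed=r).idxmax() == "L. crispatus"
                   for _ in range(200))
        assert hits >= 190  # >= 95% of draws

    def test_cst_iv_more_diverse_than_cst_i(self):
        def shannon(v):
            p = v[v > 0]
            return -np.sum(p * np.log(p))
        r = np.random.default_rng(13)
        h1 = np.mean([shannon(simulate_composition("I", seed=r).to_numpy())
                      for _ in range(100)])
        h4 = np.mean([shannon(simulate_composition("IV", seed=r).to_numpy())
                      for _ in range(100)])
        assert h4 > h1

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown CST"):
            simulate_composition("VI", seed=0)

    def test_table_rows_sum_to_one(self):
        t = simulate_composition_table(["I", "IV", "III"], seed=0)
        np.testing.assert_allclose(t.sum(axis=1), 1.0, atol=1e-9)


class TestSimulateCohort:
    def test_identity_transitions_freeze_cst(self):
        tm = pd.DataFrame(np.eye(5), index=list("IIIIV"),
                          columns=list("IIIIV"))
        tm.index = tm.columns = ["I", "II", "III", "IV", "V"]
        cohort = simulate_cohort(CohortConfig(
            n_participants=15, cst_transition_matrix=tm, seed=2))
        for _, grp in cohort.true_cst.groupby("participant_id"):
            assert grp["cst"].nunique() == 1

    def test_zero_risk_means_no_preterm(self):
        cfg = CohortConfig(n_participants=25, seed=3,
                           preterm_risk_by_cst={c: 0.0 for c in
                                                ("I", "II", "III", "IV", "V")})
        cohort = simulate_cohort(cfg)
        assert (cohort.participants["outcome"] == "term").all()

    def test_configured_risk_ratio_recovered(self):
        # risk(IV) = 0.4 vs 0.05 elsewhere -> RR 8 for IV-exposure
        cfg = CohortConfig(
            n_participants=500, seed=5, attrition_rate=0.0,
            preterm_risk_by_cst={"I": 0.05, "II": 0.05, "III": 0.05,
                                 "IV": 0.4, "V": 0.05})
        cohort = simulate_cohort(cfg)
        exposed_pids = set(
            cohort.true_cst.loc[cohort.true_cst["cst"] == "IV",
                                "participant_id"])
        p = cohort.participants
        exp = p["participant_id"].isin(exposed_pids)
        risk_exp = (p.loc[exp, "outcome"] == "preterm").mean()
        risk_unexp = (p.loc[~exp, "outcome"] == "preterm").mean()
        rr = risk_exp / risk_unexp
        assert 8.0 * 0.7 < rr < 8.0 * 1.3

    def test_fixed_seed_reproducible(self):
        a = simulate_cohort(CohortConfig(n_participants=10, seed=7))
        b = simulate_cohort(CohortConfig(n_participants=10, seed=7))
        pd.testing.assert_frame_equal(a.metadata, b.metadata)
        pd.testing.assert_frame_equal(a.compositions, b.compositions)

    def test_transition_matrix_rows_validated(self):
        tm = DEFAULT_TRANSITIONS.copy()
        tm.iloc[0, 0] += 0.1
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_cohort(CohortConfig(n_participants=5,
                                         cst_transition_matrix=tm))
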