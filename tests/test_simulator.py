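"""Dipole forward model, lead derivation, population and survival generators."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ecgvae import simulator as sim
from ecgvae.errors import MissingElectrode, SingularPoint
from ecgvae.preprocess import LEAD_NAMES
from ecgvae.survival import concordance_index, records_to_arrays


def default_subject(**kwargs):
    defaults = dict(
        subject_id="s0",
        pose=sim.default_pose(),
        layout=sim.template_layout(),
        age=60.0,
        sex=0,
        bmi=27.0,
        trajectory=sim.default_trajectory(),
    )
    defaults.update(kwargs)
    return sim.SyntheticSubject(**defaults)


class TestDipolePotential:
    def test_perpendicular_moment_gives_zero(self):
        assert sim.dipole_potential([0, 0, 1], [0, 0, 0], [1, 0, 0], sigma=1.0) == 0.0

    def test_closed_form_unit_case(self):
        """|p| = 1 aligned with unit displacement, sigma = 1/(4 pi) -> phi = 1."""
        phi = sim.dipole_potential([1, 0, 0], [0, 0, 0], [1, 0, 0],
                                   sigma=1.0 / (4.0 * np.pi))
        assert phi == pytest.approx(1.0, rel=1e-12)

    def test_inverse_square_scaling(self):
        p, src = [0.3, -0.2, 0.9], [0, 0, 0]
        near = sim.dipole_potential(p, src, [0.1, 0.1, 0.1])
        far = sim.dipole_potential(p, src, [0.2, 0.2, 0.2])
        assert far == pytest.approx(near / 4.0, rel=1e-12)

    def test_singular_point_raises(self):
        with pytest.raises(SingularPoint):
            sim.dipole_potential([1, 0, 0], [0, 0, 0], [0, 0, 1e-9])


class TestLeadVoltages:
    def test_direct_substitution(self):
        phis = {n: 0.0 for n in sim.ELECTRODE_NAMES}
        phis["LA"] = 1.0
        leads = sim.lead_voltages(phis)
        assert leads[LEAD_NAMES.index("I")] == 1.0
        assert leads[LEAD_NAMES.index("II")] == 0.0
        assert leads[LEAD_NAMES.index("III")] == -1.0

    def test_einthoven_and_goldberger_identities_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            phis = {n: rng.normal(size=7) for n in sim.ELECTRODE_NAMES}
            L = sim.lead_voltages(phis)
            assert np.array_equal(L[2], L[1] - L[0])          # III = II - I
            assert np.all((L[3] + L[4]) + L[5] == 0.0)        # aVR+aVL+aVF = 0

    def test_matches_naive_formula_oracle(self):
        rng = np.random.default_rng(1)
        phis = {n: rng.normal(size=11) for n in sim.ELECTRODE_NAMES}
        L = sim.lead_voltages(phis)
        ra, la, ll = phis["RA"], phis["LA"], phis["LL"]
        wct = (ra + la + ll) / 3.0
        naive = [la - ra, ll - ra, ll - la,
                 ra - (la + ll) / 2, la - (ra + ll) / 2, ll - (ra + la) / 2]
        naive += [phis[v] - wct for v in ("V1", "V2", "V3", "V4", "V5", "V6")]
        for got, want in zip(L, naive):
            assert np.allclose(got, want, atol=1e-14)

    def test_missing_electrode_raises(self):
        phis = {n: 0.0 for n in sim.ELECTRODE_NAMES if n != "V3"}
        with pytest.raises(MissingElectrode):
            sim.lead_voltages(phis)


class TestSimulateBeat:
    def test_zero_trajectory_gives_zero_beat(self):
        traj = sim.default_trajectory(global_scale=0.0)
        beat = sim.simulate_beat(default_subject(trajectory=traj))
        assert np.all(beat.signals == 0.0)

    def test_lead_identities_hold_on_simulated_beats(self):
        rng = np.random.default_rng(2)
        for subj in sim.sample_population(20, rng):
            s = sim.simulate_beat(subj).signals
            assert np.array_equal(s[2], s[1] - s[0])
            assert np.all((s[3] + s[4]) + s[5] == 0.0)

    def test_rigid_motion_covariance(self):
        """Jointly rotating heart and electrodes leaves every lead unchanged."""
        subj = default_subject()
        base = sim.simulate_beat(subj).signals
        rng = np.random.default_rng(3)
        for _ in range(5):
            Q = Rotation.random(random_state=rng).as_matrix()
            shift = rng.uniform(-50, 50, 3)
            pose2 = sim.pose_from_rotation(
                Q @ subj.pose.rotation, Q @ subj.pose.position + shift
            )
            layout2 = sim.ElectrodeLayout.from_array(
                subj.layout.as_array() @ Q.T + shift
            )
            moved = sim.simulate_beat(default_subject(pose=pose2, layout=layout2)).signals
            assert np.allclose(moved, base, atol=1e-9)

    def test_amplitude_scaling_is_exact(self):
        subj = default_subject()
        base = sim.simulate_beat(subj).signals
        doubled = sim.simulate_beat(
            default_subject(trajectory=subj.trajectory.scaled(2.0))
        ).signals
        assert np.allclose(doubled, 2.0 * base, rtol=1e-12)

    def test_long_axis_rotation_monotone_in_v4(self):
        amps = []
        for deg in (-40, -20, 0, 20, 40):
            pose = sim.rotate_pose(sim.default_pose(), "z", deg)
            beat = sim.simulate_beat(default_subject(pose=pose))
            amps.append(sim.r_wave_amplitude(beat.signals, "V4"))
        diffs = np.diff(amps)
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_default_r_wave_near_one_mv(self):
        """Calibration: lead II R wave sits near 100 raw units (1 mV)."""
        beat = sim.simulate_beat(default_subject())
        assert 50 < sim.r_wave_amplitude(beat.signals, "II") < 200

    def test_noise_requires_rng_and_is_reproducible(self):
        subj = default_subject()
        with pytest.raises(ValueError):
            sim.simulate_beat(subj, noise_sd=1.0)
        a = sim.simulate_beat(subj, noise_sd=1.0, rng=np.random.default_rng(4)).signals
        b = sim.simulate_beat(subj, noise_sd=1.0, rng=np.random.default_rng(4)).signals
        assert np.array_equal(a, b)


class TestPopulation:
    def test_same_seed_identical_population(self):
        a = sim.sample_population(20, np.random.default_rng(5))
        b = sim.sample_population(20, np.random.default_rng(5))
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.pose.position, sb.pose.position)
            assert np.array_equal(sa.layout.as_array(), sb.layout.as_array())
            assert sa.age == sb.age and sa.sex == sb.sex

    def test_torso_shell_and_demographic_invariants(self):
        subjects = sim.sample_population(1000, np.random.default_rng(6))
        cfg = sim.PopulationConfig()
        for s in subjects:
            dists = np.linalg.norm(s.layout.as_array() - s.pose.position, axis=1)
            assert np.all(dists > 100.0) and np.all(dists < 400.0)  # 0.1-0.4 m
            assert 40.0 <= s.age <= 80.0
            assert np.all(np.abs(s.pose.position) <= cfg.position_jitter_mm)

    def test_frames_are_rotations(self):
        for s in sim.sample_population(50, np.random.default_rng(7)):
            R = s.pose.rotation
            assert np.allclose(R.T @ R, np.eye(3), atol=1e-12)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)


class TestSimulateSurvival:
    def test_null_hazard_gives_chance_concordance(self):
        """With all betas zero, any score ranks event times at C = 0.5."""
        cs = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            subjects = sim.sample_population(2000, rng)
            beats = np.stack([sim.simulate_beat(s).signals for s in subjects])
            recs = sim.simulate_survival(
                subjects, rng, betas={"r_amp_ii": 0.0}, clean_beats=beats,
                censor_frac=0.0,
            )
            times, events = records_to_arrays(recs)
            score = rng.uniform(size=2000)
            cs.append(concordance_index(score, times, events))
        assert np.mean(cs) == pytest.approx(0.5, abs=0.02)

    def test_single_strong_feature_matches_direct_simulation_oracle(self):
        """C of the true feature ranking agrees with a large-n oracle."""
        rng = np.random.default_rng(8)
        subjects = sim.sample_population(5000, rng)
        beats = np.stack([sim.simulate_beat(s).signals for s in subjects])
        recs = sim.simulate_survival(
            subjects, rng, betas={"r_amp_ii": 2.0}, censor_frac=0.0,
            clean_beats=beats,
        )
        times, events = records_to_arrays(recs)
        feat = np.array([sim.r_wave_amplitude(b, "II") for b in beats])
        c = concordance_index(feat, times, events)
        # oracle: resimulate event times for the same standardized feature
        x = 2.0 * (feat - feat.mean()) / feat.std()
        t2 = np.random.default_rng(9).exponential(np.exp(-x))
        c_oracle = concordance_index(x, t2, np.ones_like(x))
        assert c == pytest.approx(c_oracle, abs=0.02)

    def test_censoring_fraction_hits_target(self):
        rng = np.random.default_rng(10)
        subjects = sim.sample_population(2000, rng)
        beats = np.stack([sim.simulate_beat(s).signals for s in subjects])
        recs = sim.simulate_survival(subjects, rng, censor_frac=0.7, clean_beats=beats)
        _, events = records_to_arrays(recs)
        assert 0.65 <= 1.0 - events.mean() <= 0.75

    def test_true_log_hazard_stored_and_events_labeled(self):
        rng = np.random.default_rng(11)
        subjects = sim.sample_population(100, rng)
        beats = np.stack([sim.simulate_beat(s).signals for s in subjects])
        recs = sim.simulate_survival(subjects, rng, clean_beats=beats)
        assert all(np.isfinite(s.true_log_hazard) for s in subjects)
        for r in recs:
            assert (r.subtype is not None) == bool(r.event)
            assert r.time > 0


class TestCohort:
    def test_cohort_reproducible_and_consistent(self):
        a = sim.simulate_cohort(80, seed=12)
        b = sim.simulate_cohort(80, seed=12)
        assert np.array_equal(a.beats, b.beats)
        assert [r.time for r in a.records] == [r.time for r in b.records]
        assert a.beats.shape == (80, 12, 400)

    def test_condition_matrix_blocks(self):
        coh = sim.simulate_cohort(10, seed=13)
        conds = coh.conditions(("heart_position", "heart_orientation", "sex", "age"))
        assert conds.shape == (10, 8)
        full = coh.conditions(("electrodes",))
        assert full.shape == (10, 30)
        assert coh.conditions(()).shape == (10, 0)
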