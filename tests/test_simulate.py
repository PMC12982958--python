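"""Generator laws and reproducibility of the synthetic cohort."""

import numpy as np
import pytest

from kneeprop import protocol
from kneeprop.simulate import (
    ParticipantProfile,
    SynergyGroundTruth,
    default_synergy_truth,
    gen_cohort,
    gen_emg,
    gen_questionnaires,
    gen_trajectory,
    make_profiles,
)
from kneeprop.synergy import fit_nmf


class TestTrajectoryLaws:
    def test_zero_noise_holds_hit_targets(self):
        prof = ParticipantProfile(id="P01", group="CG", error_bias=0.0,
                                  error_sd=1e-12, motor_noise_sd=0.0, seed=0)
        sched = protocol.test_schedule("pretest_squat", rng_seed=1)
        series, truth = gen_trajectory(sched, prof, rng=np.random.default_rng(0))
        for rec in truth:
            assert rec["AKA"] == pytest.approx(rec["TKA"], abs=1e-6)

    def test_learning_gain_halves_error(self):
        """With gain 0.5 the post-phase expected |error| is half the
        pre-phase value (law of the generator, 300 draws)."""
        sched = protocol.test_schedule("pretest_squat", n=1, rng_seed=0)
        pre_errs, post_errs = [], []
        for seed in range(300):
            prof = ParticipantProfile(id="P01", group="EG", error_bias=6.0,
                                      error_sd=2.0, learning_gain=0.5, seed=seed)
            _, tr_pre = gen_trajectory(sched, prof, phase="pre",
                                       rng=np.random.default_rng(seed))
            _, tr_post = gen_trajectory(sched, prof, phase="post",
                                        rng=np.random.default_rng(seed))
            pre_errs.append(abs(tr_pre[0]["error"]))
            post_errs.append(abs(tr_post[0]["error"]))
        ratio = np.mean(post_errs) / np.mean(pre_errs)
        assert ratio == pytest.approx(0.5, abs=0.05)

    def test_control_group_gain_not_applied(self):
        prof = ParticipantProfile(id="P01", group="CG", error_bias=6.0,
                                  error_sd=2.0, learning_gain=0.9, seed=1)
        sched = protocol.test_schedule("pretest_squat", n=1, rng_seed=0)
        _, pre = gen_trajectory(sched, prof, phase="pre", rng=np.random.default_rng(5))
        _, post = gen_trajectory(sched, prof, phase="post", rng=np.random.default_rng(5))
        assert pre[0]["error"] == post[0]["error"]

    def test_seed_determinism(self):
        prof = ParticipantProfile(id="P01", group="EG", error_bias=3.0, seed=9)
        sched = protocol.test_schedule("pretest_stretch", rng_seed=2)
        a, _ = gen_trajectory(sched, prof, rng=np.random.default_rng(9))
        b, _ = gen_trajectory(sched, prof, rng=np.random.default_rng(9))
        np.testing.assert_array_equal(a.included_deg, b.included_deg)

    def test_hold_error_moments_converge(self):
        """Empirical mean/SD of hold errors match the profile parameters
        within 3 standard errors at n=500."""
        sched = protocol.test_schedule("pretest_squat", n=1, rng_seed=0)
        errs = []
        for seed in range(500):
            prof = ParticipantProfile(id="P", group="CG", error_bias=4.0,
                                      error_sd=3.0, seed=seed)
            _, tr = gen_trajectory(sched, prof, rng=np.random.default_rng(seed))
            errs.append(tr[0]["error"])
        errs = np.asarray(errs)
        assert abs(errs.mean() - 4.0) < 3 * 3.0 / np.sqrt(500)
        assert abs(errs.std(ddof=1) - 3.0) < 3 * 3.0 / np.sqrt(2 * 499)


class TestEMGGenerator:
    def test_rank3_noise_free_vaf(self, rank3_emg):
        emg, _ = rank3_emg
        model = fit_nmf(emg.data.T, k=3, restarts=3, seed=0, max_iter=500)
        assert model.vaf >= 0.999

    def test_seed_determinism(self, fish_events):
        truth = default_synergy_truth(k=3, noise_sd=0.05)
        a = gen_emg(fish_events, truth, fs=500.0, rng=np.random.default_rng(4))
        b = gen_emg(fish_events, truth, fs=500.0, rng=np.random.default_rng(4))
        np.testing.assert_array_equal(a.data, b.data)

    def test_nonnegative_output(self, fish_events):
        truth = default_synergy_truth(k=2, noise_sd=0.5)
        emg = gen_emg(fish_events, truth, fs=200.0, rng=np.random.default_rng(0))
        assert np.all(emg.data >= 0.0)

    def test_column_norms_validated(self):
        W = np.abs(np.random.default_rng(0).normal(size=(7, 3)))
        with pytest.raises(ValueError, match="unit norm"):
            SynergyGroundTruth(W_true=W)


class TestCohort:
    def test_default_sizes(self):
        cohort = gen_cohort(seed=0, with_imu=False, with_emg=False)
        assert len(cohort.participants) == 14
        groups = [p.profile.group for p in cohort.participants]
        assert groups.count("EG") == 7 and groups.count("CG") == 7

    def test_effect_reaches_eg_only(self):
        cohort = gen_cohort(seed=0, effect=0.6, with_imu=False, with_emg=False)
        for p in cohort.participants:
            expected = 0.6 if p.profile.group == "EG" else 0.0
            assert p.profile.learning_gain == expected

    def test_byte_identical_regeneration(self, tmp_path):
        a_dir, b_dir = tmp_path / "a", tmp_path / "b"
        for d in (a_dir, b_dir):
            gen_cohort(n_eg=1, n_cg=1, seed=77, with_imu=True, with_emg=True,
                       emg_fs=200.0).write(d)
        files_a = sorted(p.relative_to(a_dir) for p in a_dir.rglob("*") if p.is_file())
        files_b = sorted(p.relative_to(b_dir) for p in b_dir.rglob("*") if p.is_file())
        assert files_a == files_b
        for rel in files_a:
            assert (a_dir / rel).read_bytes() == (b_dir / rel).read_bytes(), rel

    def test_calibration_buffers_long_enough(self):
        cohort = gen_cohort(n_eg=1, n_cg=1, seed=0, with_imu=True, with_emg=False)
        p = cohort.participants[0]
        for recs in p.imu.values():
            for stage in ("flat", "upright"):
                for stream in recs[stage].values():
                    assert len(stream) >= 1000

    def test_profiles_seeded_below_2_31(self):
        profiles = make_profiles(3, 3, 0.5, np.random.SeedSequence(5))
        assert all(0 <= p.seed < 2**31 for p in profiles)


class TestQuestionnaires:
    def test_bounds(self):
        profiles = make_profiles(2, 2, 0.5, np.random.SeedSequence(0))
        imi, ueq = gen_questionnaires(profiles, rng=np.random.default_rng(0))
        assert imi["value"].between(1, 7).all()
        assert ueq["value"].between(-3, 3).all()

    def test_all_max_setting(self):
        profiles = make_profiles(1, 1, 0.5, np.random.SeedSequence(0))
        imi, ueq = gen_questionnaires(profiles, rng=np.random.default_rng(0), all_max=True)
        assert (imi["value"] == 7).all()
        assert (ueq["value"] == 3).all()

    def test_determinism(self):
        profiles = make_profiles(2, 2, 0.5, np.random.SeedSequence(3))
        a = gen_questionnaires(profiles, rng=np.random.default_rng(8))
        b = gen_questionnaires(profiles, rng=np.random.default_rng(8))
        assert a[0].equals(b[0]) and a[1].equals(b[1])
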