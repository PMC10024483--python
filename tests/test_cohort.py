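"""Synthetic cohort generation, group allocation, intervention, trace simulation."""

import dataclasses

import numpy as np
import pytest

import sprintfv as s
from sprintfv.cohort import CohortConfig, GroupEffect
from sprintfv.errors import ConfigError, InvalidInputError


def small_config(**kw):
    base = dict(
        n_total=4,
        group_sizes={"CST": 2, "MST": 2},
    )
    base.update(kw)
    return CohortConfig(**base)


class TestGenerate:
    def test_fixed_seed_reproducible(self):
        c1 = s.generate_cohort(CohortConfig(), 7)
        c2 = s.generate_cohort(CohortConfig(), 7)
        assert c1 == c2

    def test_sample_moments_within_three_se(self):
        cfg = CohortConfig(n_total=2000, group_sizes={"CST": 1000, "MST": 1000})
        cohort = s.generate_cohort(cfg, 11)
        mass = np.array([a.athlete.body_mass for a in cohort])
        assert abs(mass.mean() - 58.5) < 3 * 10.0 / np.sqrt(2000) + 0.05

    def test_zero_sds_identical_athletes(self):
        cfg = small_config(
            body_mass=(58.5, 0.0), stature=(1.74, 0.0),
            pre_f0_rel={"CST": (5.18, 0.0), "MST": (5.18, 0.0)},
            pre_v0={"CST": (8.31, 0.0), "MST": (8.31, 0.0)},
        )
        cohort = s.generate_cohort(cfg, 0)
        assert len({(a.athlete.body_mass, a.pre.f0_rel, a.pre.v0) for a in cohort}) == 1

    def test_impossible_truncation_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(body_mass=(20.0, 1.0))
        with pytest.raises(ConfigError):
            CohortConfig(group_sizes={"CST": 10, "MST": 8})


class TestAllocate:
    def test_identical_times_equal_group_means(self):
        times = np.full(22, 4.0)
        g = np.array(s.allocate_groups(times, sizes=(14, 8), seed=3))
        assert times[g == "CST"].mean() == times[g == "MST"].mean()
        assert (g == "CST").sum() == 14 and (g == "MST").sum() == 8

    def test_adjacent_pairing_with_equal_targets(self):
        times = [3.9, 4.0, 4.1, 4.2]
        for seed in range(8):
            g = s.allocate_groups(times, sizes=(2, 2), seed=seed)
            for grp in ("CST", "MST"):
                mine = sorted(t for t, lab in zip(times, g) if lab == grp)
                assert mine[0] in (3.9, 4.0) and mine[1] in (4.1, 4.2)

    def test_monte_carlo_balance(self, rng):
        """Group pre-time means differ by < 0.3 SD in at least 95% of allocations."""
        ok = 0
        for i in range(500):
            t = rng.normal(4.05, 0.21, 22)
            g = np.array(s.allocate_groups(t, sizes=(14, 8), seed=rng))
            if abs(t[g == "CST"].mean() - t[g == "MST"].mean()) < 0.3 * 0.21:
                ok += 1
        assert ok / 500 >= 0.95

    def test_too_few_athletes(self):
        with pytest.raises(InvalidInputError):
            s.allocate_groups([4.0], sizes=(1, 0))


class TestIntervention:
    def test_zero_effects_post_equals_pre(self):
        cohort = s.generate_cohort(small_config(), 0)
        out = s.apply_intervention(cohort, {"CST": GroupEffect(), "MST": GroupEffect()}, 0)
        for sa in out:
            assert sa.post == sa.pre

    def test_deterministic_multiplicative_effect(self):
        cohort = s.generate_cohort(small_config(), 0)
        eff = {"CST": GroupEffect(f0_rel_pct=(11.19, 0.0)),
               "MST": GroupEffect(f0_rel_pct=(11.19, 0.0))}
        out = s.apply_intervention(cohort, eff, 0)
        for sa in out:
            assert sa.post.f0_rel == pytest.approx(1.1119 * sa.pre.f0_rel, rel=1e-12)
            assert sa.post.v0 == pytest.approx(sa.pre.v0, rel=1e-12)

    def test_population_mean_effect_recovered(self, rng):
        cfg = CohortConfig(n_total=500, group_sizes={"CST": 500, "MST": 0})
        cohort = s.generate_cohort(cfg, 5)
        out = s.apply_intervention(
            cohort, {"CST": GroupEffect(f0_rel_pct=(11.19, 12.52))}, 5)
        pct = [100 * (sa.post.f0_rel / sa.pre.f0_rel - 1) for sa in out]
        assert np.mean(pct) == pytest.approx(11.19, abs=1.5)


class TestSimulateTrace:
    def test_mono_exp_noiseless_roundtrip(self, athlete):
        prof = s.GroundTruthProfile(f0_rel=6.648, v0=8.31)  # MSS 8.31, tau 1.25
        tr = s.simulate_trace(prof, athlete, noise_sd=0.0, overrun=1.5, seed=0)
        trimmed, _ = s.trim_trace(tr)
        fit = s.fit_sprint_model(trimmed)
        assert fit.mss == pytest.approx(prof.mss, abs=1e-6)
        assert fit.tau == pytest.approx(prof.tau, abs=1e-6)

    def test_ode_mode_plateaus_at_drag_corrected_terminal_velocity(self, athlete):
        prof = s.GroundTruthProfile(f0_rel=5.18, v0=8.31)
        k = s.drag_model(athlete, s.air_density(760, 20)).k_aero
        f0 = prof.f0_rel * athlete.body_mass
        v_term = (-f0 / prof.v0 + np.sqrt((f0 / prof.v0) ** 2 + 4 * k * f0)) / (2 * k)
        assert v_term == pytest.approx(7.89, abs=0.005)
        tr = s.simulate_trace(prof, athlete, noise_sd=0.0, mode="linear_fv_ode",
                              overrun=15.0, seed=0)
        assert tr.velocity.max() == pytest.approx(v_term, abs=0.01)

    def test_ode_pipeline_recovers_profile_within_three_percent(self, athlete):
        """Mono-exponential fit of the drag-ODE trace: bounded model mismatch."""
        prof = s.GroundTruthProfile(f0_rel=5.18, v0=8.31)
        tr = s.simulate_trace(prof, athlete, noise_sd=0.0, mode="linear_fv_ode",
                              overrun=0.5, seed=0)
        trimmed, _ = s.trim_trace(tr)
        fit = s.fit_sprint_model(trimmed)
        fv = s.derive_fv_profile(fit, athlete, sprint_distance=20.0)
        assert fv.f0_rel == pytest.approx(prof.f0_rel, rel=0.03)
        assert fv.v0 == pytest.approx(prof.v0, rel=0.03)

    def test_non_finite_profile_rejected(self, athlete):
        with pytest.raises(InvalidInputError):
            s.simulate_trace(
                dataclasses.replace(s.GroundTruthProfile(5.0, 8.0), f0_rel=np.nan),
                athlete)

    def test_pre_onset_segment_and_delay(self, athlete, rng):
        prof = s.GroundTruthProfile(5.18, 8.31)
        tr = s.simulate_trace(prof, athlete, noise_sd=0.05, seed=rng,
                              pre_onset_duration=1.0, onset_delay=0.1)
        trimmed, rep = s.trim_trace(tr)
        assert rep.n_leading_removed >= 30  # the stationary second was removed
        fit = s.fit_sprint_model(trimmed)
        assert fit.mss == pytest.approx(8.31, rel=0.02)


def test_simulate_study_shape_and_determinism():
    cfg = small_config()
    tr1, co1 = s.simulate_study(cfg, 42)
    tr2, co2 = s.simulate_study(cfg, 42)
    assert len(tr1) == 4 * 2 * 3
    assert co1 == co2
    assert all(np.array_equal(a.velocity, b.velocity) for a, b in zip(tr1, tr2))
    sessions = {(t.athlete_id, t.session, t.trial_index) for t in tr1}
    assert len(sessions) == len(tr1)
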