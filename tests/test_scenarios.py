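"""Invasion scenarios: parameter schedules, integration, extinction rules."""

import numpy as np
import pytest

from cctradeoff import (
    Metacommunity,
    PulseSchedule,
    ScenarioConfig,
    apply_scenario,
    detect_extinctions,
    eventual_extinctions,
    integrate,
    run_invasion,
    solve_equilibrium,
)
from cctradeoff.scenarios import integrate_cascade


class TestApplyScenario:
    def test_neutral_config_is_identity(self, five_species_ensemble):
        mc = five_species_ensemble[0]
        param = apply_scenario(mc, ScenarioConfig(invader_rank=3))
        assert len(param.segments) == 1
        seg = param.segments[0][2]
        assert np.array_equal(seg.c, mc.c)
        assert np.array_equal(seg.m, mc.m)
        assert np.array_equal(seg.h, mc.h)
        assert seg.off_surface_rank is None

    def test_baseline_not_modified(self, five_species_ensemble):
        mc = five_species_ensemble[0]
        cfg = ScenarioConfig(invader_rank=2, h_level=0.05,
                             invader_mortality_delta=0.01,
                             disturbance_mortality=0.2)
        apply_scenario(mc, cfg)
        assert np.all(mc.h == 0.0)
        assert np.all(mc.m == 0.05)

    def test_disturbance_replaces_every_mortality(self, five_species_ensemble):
        mc = five_species_ensemble[0]
        cfg = ScenarioConfig(invader_rank=2, disturbance_mortality=0.35)
        seg = apply_scenario(mc, cfg).segments[0][2]
        assert np.all(seg.m == 0.35)

    def test_enemy_release_lowers_only_invader(self, five_species_ensemble):
        mc = five_species_ensemble[0]
        cfg = ScenarioConfig(invader_rank=3, invader_mortality_delta=0.02)
        seg = apply_scenario(mc, cfg).segments[0][2]
        assert seg.m[2] == pytest.approx(0.03)
        assert np.all(np.delete(seg.m, 2) == 0.05)
        assert seg.off_surface_rank == 3

    def test_pulse_schedule_is_piecewise_constant(self, five_species_ensemble):
        mc = five_species_ensemble[0]
        cfg = ScenarioConfig(
            invader_rank=2,
            h_pulse=PulseSchedule(onset=0.0, duration=40.0, level=0.05),
            horizon=500.0,
        )
        param = apply_scenario(mc, cfg)
        assert [s[:2] for s in param.segments] == [(0.0, 40.0), (40.0, 500.0)]
        assert param.segments[0][2].h[1] == 0.05
        assert param.segments[1][2].h[1] == 0.0
        assert param.final.h[1] == 0.0

    def test_invalid_configs_rejected(self, five_species_ensemble):
        mc = five_species_ensemble[0]
        with pytest.raises(ValueError, match="out of range"):
            apply_scenario(mc, ScenarioConfig(invader_rank=9))
        with pytest.raises(ValueError, match="m_a"):
            apply_scenario(
                mc, ScenarioConfig(invader_rank=1,
                                   invader_mortality_delta=0.05)
            )
        with pytest.raises(ValueError):
            ScenarioConfig(invader_rank=1, h_level=-0.1)
        with pytest.raises(ValueError):
            ScenarioConfig(invader_rank=1, extinction_threshold=1.5)


class TestIntegrate:
    def test_equilibrium_start_stays_constant(self, five_species_ensemble):
        mc = five_species_ensemble[0]
        cfg = ScenarioConfig(invader_rank=1, horizon=1000.0)
        traj = integrate(apply_scenario(mc, cfg), cfg=cfg)
        eq = solve_equilibrium(mc).p
        np.testing.assert_allclose(
            traj.occupancy, np.broadcast_to(eq, traj.occupancy.shape),
            atol=1e-8,
        )

    def test_halved_tolerances_change_little(self, five_species_ensemble):
        mc = five_species_ensemble[1]
        cfg = ScenarioConfig(invader_rank=3, h_level=0.03, horizon=2000.0)
        param = apply_scenario(mc, cfg)
        a = integrate(param, cfg=cfg, rtol=1e-10, atol=1e-14)
        b = integrate(param, cfg=cfg, rtol=5e-11, atol=5e-15)
        assert np.max(np.abs(a.occupancy - b.occupancy)) < 1e-6

    def test_running_min_ratio_non_increasing(self, five_species_ensemble):
        mc = five_species_ensemble[1]
        cfg = ScenarioConfig(invader_rank=2, h_level=0.05, horizon=3000.0)
        traj = integrate(apply_scenario(mc, cfg), cfg=cfg)
        assert np.all(np.diff(traj.running_min_ratio, axis=0) <= 1e-12)

    def test_cascade_agrees_with_joint_integration(self, five_species_ensemble):
        mc = five_species_ensemble[2]
        cfg = ScenarioConfig(invader_rank=3, h_level=0.04, horizon=500.0,
                             n_output=16)
        param = apply_scenario(mc, cfg)
        joint = integrate(param, cfg=cfg)
        casc = integrate_cascade(param, cfg=cfg)
        np.testing.assert_allclose(casc.occupancy, joint.occupancy, atol=1e-7)


class TestHierarchyIndependence:
    def test_superiors_bit_identical_under_manipulation(
        self, five_species_ensemble
    ):
        """Species outrank the invader -> their computed trajectories are
        bit-for-bit unchanged by any manipulation of it (cascade route)."""
        mc = five_species_ensemble[0]
        a = 4
        base_cfg = ScenarioConfig(invader_rank=a, horizon=800.0, n_output=32)
        inv_cfg = ScenarioConfig(invader_rank=a, h_level=0.08,
                                 invader_mortality_delta=0.02,
                                 horizon=800.0, n_output=32)
        base = integrate_cascade(apply_scenario(mc, base_cfg), cfg=base_cfg)
        manip = integrate_cascade(apply_scenario(mc, inv_cfg), cfg=inv_cfg)
        sup = slice(0, a - 1)
        assert np.array_equal(base.occupancy[:, sup], manip.occupancy[:, sup])

    def test_superiors_unchanged_within_tolerance_joint(
        self, five_species_ensemble
    ):
        mc = five_species_ensemble[0]
        a = 3
        cfg = ScenarioConfig(invader_rank=a, h_level=0.08, horizon=800.0)
        res = run_invasion(mc, cfg)
        eq = solve_equilibrium(mc).p
        sup = res.trajectory.occupancy[:, : a - 1]
        np.testing.assert_allclose(
            sup, np.broadcast_to(eq[: a - 1], sup.shape), atol=1e-8
        )


class TestDetectExtinctions:
    @staticmethod
    def _traj_from_series(times, ratio, baseline):
        from cctradeoff.scenarios import Trajectory

        occ = ratio * baseline
        return Trajectory(
            times=times, occupancy=occ, baseline=baseline,
            running_min_ratio=np.minimum.accumulate(ratio, axis=0),
            step_times=times, step_ratio=ratio,
        )

    def test_strictly_below_rule_and_boundary(self):
        times = np.linspace(0.0, 10.0, 11)
        base = np.array([0.5, 0.5])
        ratio = np.ones((11, 2))
        ratio[5:, 0] = 5e-5      # dips below 1e-4
        ratio[5:, 1] = 1e-4      # exactly at the threshold
        traj = self._traj_from_series(times, ratio, base)
        recs = detect_extinctions(traj, threshold=1e-4)
        assert recs[0].extinct and not recs[1].extinct
        assert recs[1].first_crossing_time is None

    def test_extinction_is_absorbing(self):
        times = np.linspace(0.0, 10.0, 11)
        base = np.array([0.5])
        ratio = np.ones((11, 1))
        ratio[3:6, 0] = 5e-5    # dips then recovers
        traj = self._traj_from_series(times, ratio, base)
        recs = detect_extinctions(traj, threshold=1e-4)
        assert recs[0].extinct
        assert recs[0].first_crossing_time <= times[3]
        assert traj.running_min_ratio[-1, 0] < 1e-4  # verdict persists

    def test_crossing_time_matches_dynamics(self, five_species_ensemble):
        # crossing time found on the dense solution agrees with the first
        # output time whose ratio is below threshold
        mc = five_species_ensemble[1]
        cfg = ScenarioConfig(invader_rank=1, h_level=0.1, horizon=4000.0)
        res = run_invasion(mc, cfg)
        ratio = res.trajectory.ratio()
        for rec in res.records:
            if not rec.extinct:
                continue
            below = ratio[:, rec.rank - 1] < cfg.extinction_threshold
            if below.any():
                first_out = res.trajectory.times[np.argmax(below)]
                assert rec.first_crossing_time <= first_out + 1e-3


class TestRunInvasion:
    def test_neutral_scenario_no_extinctions(self, five_species_ensemble):
        mc = five_species_ensemble[0]
        res = run_invasion(mc, ScenarioConfig(invader_rank=2, horizon=500.0))
        assert res.native_extinctions == 0
        assert np.all(res.extinction_timeline == 0.0)
        assert res.eventual_native_extinctions == 0

    def test_only_inferiors_can_be_displaced(self, five_species_ensemble):
        for mc in five_species_ensemble[:4]:
            a = 3
            cfg = ScenarioConfig(invader_rank=a, h_level=0.2,
                                 invader_mortality_delta=0.03)
            mask = eventual_extinctions(mc, cfg)
            assert not mask[: a - 1].any()

    def test_sustained_scenario_matches_analytic_end_state(
        self, five_species_ensemble
    ):
        for mc in five_species_ensemble[:4]:
            cfg = ScenarioConfig(invader_rank=2, h_level=0.06,
                                 horizon=20000.0)
            res = run_invasion(mc, cfg)
            dyn = {r.rank for r in res.records
                   if r.extinct and r.rank != cfg.invader_rank}
            mask = res.eventual_extinct_mask.copy()
            mask[cfg.invader_rank - 1] = False
            analytic = {i + 1 for i in np.flatnonzero(mask)}
            assert dyn == analytic

    def test_timeline_counts_natives_only(self, five_species_ensemble):
        mc = five_species_ensemble[1]
        cfg = ScenarioConfig(invader_rank=1, h_level=0.15, horizon=5000.0)
        res = run_invasion(mc, cfg)
        assert np.all(np.diff(res.extinction_timeline) >= 0.0)
        assert res.extinction_timeline[-1] == pytest.approx(
            res.native_extinctions / (mc.N - 1)
        )

    def test_infeasible_baseline_rejected(self):
        mc = Metacommunity(c=[1.0, 4.0], m=[0.05] * 2, h=[0.0] * 2)
        with pytest.raises(ValueError, match="feasible"):
            run_invasion(mc, ScenarioConfig(invader_rank=1))


class TestMonotonicity:
    """Stronger propagule supply or enemy release displaces more natives on
    average.  Per-community counts can dip locally: crushing an intermediate
    inferior releases species ranked below it (competitive release), so only
    the ensemble-mean curve is asserted monotone."""

    @staticmethod
    def _mean_count(ensemble, cfg):
        tot = 0
        for mc in ensemble:
            mask = eventual_extinctions(mc, cfg)
            mask[cfg.invader_rank - 1] = False
            tot += mask.sum()
        return tot / len(ensemble)

    def test_first_inferior_monotonically_suppressed_in_h(
        self, five_species_ensemble
    ):
        """The invader's immediate inferior feels only pressures that grow
        with h_a, so its eventual occupancy declines monotonically (no
        release pathway exists for it)."""
        from cctradeoff.scenarios import apply_scenario

        a = 2
        for mc in five_species_ensemble:
            occ = []
            for h in np.linspace(0.0, 0.2, 9):
                cfg = ScenarioConfig(invader_rank=a, h_level=h)
                eq = solve_equilibrium(apply_scenario(mc, cfg).final)
                occ.append(eq.p[a])
            assert np.all(np.diff(occ) <= 1e-12)

    def test_strong_invasion_displaces_more_than_none(
        self, five_species_ensemble
    ):
        for cfg_hi, cfg_lo in [
            (ScenarioConfig(invader_rank=2, h_level=0.2),
             ScenarioConfig(invader_rank=2, h_level=0.0)),
            (ScenarioConfig(invader_rank=2, invader_mortality_delta=0.045),
             ScenarioConfig(invader_rank=2, invader_mortality_delta=0.0)),
        ]:
            hi = self._mean_count(five_species_ensemble, cfg_hi)
            lo = self._mean_count(five_species_ensemble, cfg_lo)
            assert lo == 0.0
            assert hi > lo

    def test_competitive_release_can_reverse_counts(self,
                                                    five_species_ensemble):
        """The release pathway is real: somewhere on a wide h grid, some
        community loses an extinction as h grows because the released
        species' eventual equilibrium climbs back above threshold."""
        reversed_somewhere = False
        for mc in five_species_ensemble:
            counts = []
            for h in np.linspace(0.0, 0.2, 9):
                cfg = ScenarioConfig(invader_rank=2, h_level=h)
                mask = eventual_extinctions(mc, cfg)
                mask[1] = False
                counts.append(mask.sum())
            if np.any(np.diff(counts) < 0):
                reversed_somewhere = True
        assert reversed_somewhere


class TestPulse:
    def test_transient_decline_then_recovery(self, five_species_ensemble):
        """A temporary propagule pulse dents inferior competitors; species
        that are not driven extinct return to baseline after it ends."""
        mc = five_species_ensemble[0]
        cfg = ScenarioConfig(
            invader_rank=2,
            h_pulse=PulseSchedule(onset=0.0, duration=100.0, level=0.05),
            horizon=20000.0,
        )
        res = run_invasion(mc, cfg)
        ratio_final = res.trajectory.ratio()[-1]
        dipped = res.trajectory.running_min_ratio[-1]
        inferior = np.arange(mc.N) >= 2
        survivors = np.array([not r.extinct for r in res.records])
        # at least one inferior competitor visibly dented
        assert np.any(dipped[inferior & survivors] < 0.9)
        # survivors recover to within 1% of baseline
        assert np.all(np.abs(ratio_final[survivors] - 1.0) < 0.01)
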