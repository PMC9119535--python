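"""Integration protocol: spin-up, forced runs, metrics, numerical checks."""

import math
import warnings
from dataclasses import replace

import numpy as np
import pytest

from coralacclim import (
    GlobalParams,
    ModelState,
    RunSettings,
    ScenarioSpec,
    TemperatureSeries,
    Trajectory,
    decline_metric,
    region_preset,
    relative_abundance,
    run,
    spin_up,
    synthetic_forcing,
    trait_change_metric,
)
from coralacclim.simulate import scaled_rhs_norm


def _constant_forcing(T, months, start=(1955, 1)):
    return TemperatureSeries(start, np.full(months, float(T)))


def _warming_forcing(reg, rise=1.85, seed=11, span=(1955, 2050)):
    return synthetic_forcing(
        ScenarioSpec(baseline_mean=reg.spinup_T, target_rise=rise, seed=seed, span=span)
    )


class TestSpinUp:
    def test_persistent_symbiosis(self, spun_up_states, region):
        st = spun_up_states[region.name]
        assert st.C > 0 and st.S > 0 and st.U > 0
        assert st.C < region.K_C

    def test_warns_when_still_drifting(self, gbr):
        with pytest.warns(RuntimeWarning, match="drifting"):
            spin_up(gbr, years=50)

    def test_consistent_with_constant_forced_run(self, gbr, params):
        # a 10-year spin-up equals a run from the published initial state
        # over 120 months of constant spin-up temperature
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            st = spin_up(gbr, params, years=10)
        state0 = ModelState(C=0.75 * gbr.K_C, S=1e-3, U=5e-7)
        settings = RunSettings(bleaching_enabled=False)
        traj = run(state0, _constant_forcing(gbr.spinup_T, 120), gbr, params, settings)
        end = traj.final_state()
        assert end.C == pytest.approx(st.C, rel=1e-12)
        assert end.S == pytest.approx(st.S, rel=1e-12)
        assert end.U == pytest.approx(st.U, rel=1e-12)

    def test_fixed_point_persists_under_constant_forcing(self, gbr, params):
        # the interior equilibrium (F = 0, dF/dU = 0, S = K_S) is found by
        # root-finding and stays put under the integrator; the 2000-year
        # protocol state is still far from it (slow trait drift)
        from scipy.optimize import fsolve

        from coralacclim import coral_fitness, fitness_gradient

        settings = RunSettings(bleaching_enabled=False)
        eps = settings.epsilon_guard
        scale = params.K_smax * gbr.K_C
        T = gbr.spinup_T

        def residual(x):
            c, u = x
            state = ModelState(C=c * gbr.K_C, S=(c + eps) * scale, U=u)
            return (
                coral_fitness(state, T, gbr, params, eps=eps),
                fitness_gradient(state, T, gbr, params, eps=eps) * 1e-4,
            )

        (c_eq, u_eq), info, ok, _ = fsolve(residual, (0.9, 1e-4), full_output=True)
        assert ok == 1
        st = ModelState(C=c_eq * gbr.K_C, S=(c_eq + eps) * scale, U=u_eq)
        assert scaled_rhs_norm(st, T, gbr, params, eps) < 1e-12
        traj = run(st, _constant_forcing(T, 120), gbr, params, settings)
        for series in (traj.C_series, traj.S_series, traj.U_series):
            assert np.max(np.abs(series / series[0] - 1.0)) < 1e-6


class TestRun:
    def test_no_acclimation_trait_constant(self, spun_up_states, gbr, params):
        reg0 = replace(gbr, N=0.0)
        st = replace(spun_up_states["GBR"])
        traj = run(st, _warming_forcing(gbr), reg0, params, RunSettings(seed=3))
        assert np.all(traj.U_series == traj.U_series[0])

    def test_symbiont_free_coral_decays_exponentially(self, gbr, params):
        # without symbionts corals die at the background mortality rate
        C0 = 0.3 * gbr.K_C
        state0 = ModelState(C=C0, S=0.0, U=5e-7)
        traj = run(
            state0,
            _constant_forcing(26.8, 1200),
            gbr,
            params,
            RunSettings(bleaching_enabled=False),
        )
        expected = C0 * math.exp(-params.M_C * 1200)
        assert traj.C_series[-1] == pytest.approx(expected, rel=1e-6)
        assert np.all(traj.S_series == 0.0)

    def test_non_negative_throughout(self, spun_up_states, region, params):
        traj = run(
            spun_up_states[region.name],
            _warming_forcing(region, rise=3.7),
            region,
            params,
            RunSettings(seed=5),
        )
        assert np.all(traj.C_series >= 0)
        assert np.all(traj.S_series >= 0)
        assert np.all(traj.U_series >= 0)

    def test_step_halving_convergence(self, spun_up_states, gbr, params):
        st = spun_up_states["GBR"]
        f = _warming_forcing(gbr, span=(1955, 1975))
        ends = []
        for nsub in (10, 20):
            traj = run(st, f, gbr, params, RunSettings(seed=2, substeps_per_month=nsub))
            ends.append(np.array([traj.C_series[-1], traj.S_series[-1], traj.U_series[-1]]))
        assert np.all(np.abs(ends[1] / ends[0] - 1.0) < 1e-5)

    def test_rk4_agrees_with_adaptive(self, spun_up_states, gbr, params):
        st = spun_up_states["GBR"]
        f = _warming_forcing(gbr, span=(1955, 1965))
        a = run(st, f, gbr, params, RunSettings(seed=2, integrator="rk4"))
        b = run(st, f, gbr, params, RunSettings(seed=2, integrator="adaptive"))
        np.testing.assert_allclose(a.C_series, b.C_series, rtol=1e-6)
        np.testing.assert_allclose(a.U_series, b.U_series, rtol=1e-6)

    def test_seeded_reproducibility(self, spun_up_states, gbr, params):
        st = spun_up_states["GBR"]
        f = _warming_forcing(gbr, rise=3.7, span=(1955, 1995))
        a = run(st, f, gbr, params, RunSettings(seed=7))
        b = run(st, f, gbr, params, RunSettings(seed=7))
        np.testing.assert_array_equal(a.C_series, b.C_series)
        np.testing.assert_array_equal(a.S_series, b.S_series)
        assert [e.reduction_drawn for e in a.events] == [
            e.reduction_drawn for e in b.events
        ]
        c = run(st, f, gbr, params, RunSettings(seed=8))
        assert len(c.events) == len(a.events)  # same trigger months
        assert any(
            x.reduction_drawn != y.reduction_drawn for x, y in zip(a.events, c.events)
        )

    def test_bleaching_off_has_no_events(self, spun_up_states, gbr, params):
        traj = run(
            spun_up_states["GBR"],
            _warming_forcing(gbr, rise=3.7),
            gbr,
            params,
            RunSettings(bleaching_enabled=False),
        )
        assert traj.events == ()

    def test_event_log_reconstructs_discontinuities(self, spun_up_states, gbr, params):
        st = spun_up_states["GBR"]
        f = _warming_forcing(gbr, rise=3.7, span=(1955, 2000))
        settings = RunSettings(seed=13)
        traj = run(st, f, gbr, params, settings)
        assert len(traj.events) > 0
        off = RunSettings(bleaching_enabled=False, seed=13)
        for ev in traj.events[:10]:
            assert ev.S_before == pytest.approx(traj.S_series[ev.time], rel=1e-12)
            assert ev.S_after == pytest.approx(
                (1 - ev.reduction_drawn / 100) * ev.S_before, rel=1e-12
            )
            # integrating the month from the post-event state reproduces the
            # stored end-of-month value
            state = ModelState(
                C=float(traj.C_series[ev.time]), S=ev.S_after, U=float(traj.U_series[ev.time])
            )
            month = TemperatureSeries(f.year_month(ev.time), f.values[ev.time : ev.time + 1])
            redo = run(state, month, gbr, params, off)
            assert redo.S_series[-1] == pytest.approx(traj.S_series[ev.time + 1], rel=1e-9)
            assert redo.C_series[-1] == pytest.approx(traj.C_series[ev.time + 1], rel=1e-9)


class TestTrajectoryAndMetrics:
    def _make_traj(self, C, U=None, start=(1980, 1)):
        n = len(C) - 1
        return Trajectory(
            start=start,
            T=np.full(n, 26.0),
            C_series=np.asarray(C, dtype=float),
            S_series=np.zeros(n + 1),
            U_series=np.asarray(U, dtype=float) if U is not None else np.ones(n + 1),
            events=(),
        )

    def test_relative_abundance_endpoints(self, gbr):
        traj = self._make_traj([gbr.K_C, 0.75 * gbr.K_C, 0.0])
        rel = relative_abundance(traj, gbr)
        np.testing.assert_allclose(rel, [100.0, 75.0, 0.0])

    def test_decline_metric_cases(self):
        months = (2100 - 1980 + 1) * 12
        base, fut = (1986, 2005), (2081, 2100)
        traj = self._make_traj(np.full(months + 1, 5.0))
        assert decline_metric(traj, base, fut) == pytest.approx(0.0)
        # future window exactly halved
        C = np.full(months + 1, 10.0)
        years = 1980 + (np.arange(months) // 12)
        C[1:][years >= 2081] = 5.0
        traj = self._make_traj(C)
        assert decline_metric(traj, base, fut) == pytest.approx(50.0)
        C = np.full(months + 1, 10.0)
        C[1:][years >= 2081] = 11.0
        traj = self._make_traj(C)
        assert decline_metric(traj, base, fut) == pytest.approx(-10.0)

    def test_trait_change_linear_ramp(self):
        months = (2100 - 1980 + 1) * 12
        U = np.linspace(1.0, 2.0, months + 1)
        traj = self._make_traj(np.ones(months + 1), U=U)
        years = 1980 + (np.arange(months) // 12)
        mb = U[1:][(years >= 1986) & (years <= 2005)].mean()
        mf = U[1:][(years >= 2081) & (years <= 2100)].mean()
        assert trait_change_metric(traj) == pytest.approx(100 * (mf / mb - 1))

    def test_uncovered_window_is_error(self):
        traj = self._make_traj(np.ones(25), start=(1990, 1))
        with pytest.raises(ValueError, match="cover"):
            decline_metric(traj)

    def test_trajectory_validation(self):
        with pytest.raises(ValueError, match="length"):
            Trajectory(
                start=(2000, 1),
                T=np.ones(12),
                C_series=np.ones(12),  # should be 13
                S_series=np.ones(13),
                U_series=np.ones(13),
                events=(),
            )

    def test_dataframe_export(self, spun_up_states, gbr, params):
        traj = run(
            spun_up_states["GBR"],
            _warming_forcing(gbr, rise=3.7, span=(1955, 1960)),
            gbr,
            params,
            RunSettings(seed=1),
        )
        df = traj.to_dataframe(K_C=gbr.K_C)
        assert list(df.columns) == [
            "month_index", "year", "month", "T_c", "C_cm2", "S_cells",
            "U_trait", "C_rel_pct", "bleached_flag",
        ]
        assert len(df) == traj.n_months
        assert df["bleached_flag"].sum() == len(traj.events)
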