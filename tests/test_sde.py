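"""Euler-Maruyama simulator: determinism, positivity, convergence, hopping."""

import numpy as np
import pytest

import stoichswitch as sw
from stoichswitch.geometry import integrate
from stoichswitch.sde import (_debounced_runs, _rep_seed, extinction_time,
                              simulate)


class TestSimulate:
    def test_zero_noise_holds_fixed_point(self, params3, stable3):
        e4 = stable3[1]
        traj = sw.simulate(params3, sw.NoiseSpec(0, 0), e4.location, 100.0,
                           h=1e-3, seed=0)
        assert np.linalg.norm(traj.states[-1] - e4.location) < 1e-6

    def test_bit_reproducible(self, params3, stable3):
        kw = dict(t_end=50.0, h=1e-3, seed=123)
        a = sw.simulate(params3, sw.NoiseSpec(0.01, 0.02), stable3[0].location, **kw)
        b = sw.simulate(params3, sw.NoiseSpec(0.01, 0.02), stable3[0].location, **kw)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.regime, b.regime)

    def test_different_seeds_differ(self, params3, stable3):
        kw = dict(t_end=10.0, h=1e-3)
        a = sw.simulate(params3, sw.NoiseSpec(0.01, 0.01), stable3[0].location,
                        seed=1, **kw)
        b = sw.simulate(params3, sw.NoiseSpec(0.01, 0.01), stable3[0].location,
                        seed=2, **kw)
        assert not np.array_equal(a.states, b.states)
        assert a.states.shape == b.states.shape

    def test_positivity_under_violent_noise(self, params3):
        traj = sw.simulate(params3, sw.NoiseSpec(2.0, 2.0), (0.01, 0.01),
                           200.0, h=1e-3, seed=5)
        assert traj.states.min() > 0.0

    def test_regime_labels_track_branch_line(self, params3, stable3):
        traj = sw.simulate(params3, sw.NoiseSpec(0.005, 0.005),
                           stable3[1].location, 20.0, h=1e-3, seed=9)
        sums = traj.states.sum(axis=1)
        assert np.array_equal(traj.regime, (sums > params3.p).astype(np.uint8))

    def test_euler_order_one(self, params3):
        z0 = np.array([0.3, 0.3])
        ref = integrate(params3, z0, 10.0).y[:, -1]
        errs = [np.linalg.norm(
            sw.simulate(params3, sw.NoiseSpec(0, 0), z0, 10.0, h=h, seed=0)
            .states[-1] - ref) for h in (1e-2, 1e-3)]
        assert errs[0] / errs[1] == pytest.approx(10.0, rel=0.3)

    def test_rejects_bad_inputs(self, params3):
        with pytest.raises(ValueError):
            sw.simulate(params3, sw.NoiseSpec(0, 0), (0.0, 0.1), 1.0)
        with pytest.raises(ValueError):
            sw.NoiseSpec(-0.1, 0.0)


class TestEnsemble:
    def test_zero_noise_collapses_to_attractor(self, params3, stable3):
        e4 = stable3[1]
        samp = sw.ensemble_sample(params3, sw.NoiseSpec(0, 0), e4.location,
                                  5, 100.0, h=1e-3, seed=0)
        assert np.abs(samp - e4.location).max() < 1e-6

    def test_covariance_scales_with_noise_squared(self, params3, stable3):
        # log-log slope of tr(cov) vs eps must be ~2; common seeds across
        # eps make the ratio nearly deterministic
        e4 = stable3[1]
        eps_grid = (1e-3, 2e-3, 4e-3)
        tr = []
        for eps in eps_grid:
            samp = sw.ensemble_sample(params3, sw.NoiseSpec(eps, eps),
                                      e4.location, 40, 120.0, burn_in=60.0,
                                      thin=20.0, h=1e-3, seed=77)
            tr.append(np.trace(np.cov(samp.T)))
        slope = np.polyfit(np.log(eps_grid), np.log(tr), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.1)

    def test_rep_seeds_stay_in_range(self):
        seeds = {_rep_seed(s, i) for s in (0, 1, 2**20) for i in range(100)}
        assert all(0 <= v < 2**31 for v in seeds)
        assert len(seeds) == 300


class TestTransitionStats:
    def test_deterministic_settling_no_hops(self, params3, separatrix3,
                                            attractors3, stable3):
        traj = sw.simulate(params3, sw.NoiseSpec(0, 0), stable3[1].location,
                           100.0, h=1e-3, seed=0)
        st = sw.transition_stats(traj, separatrix3, attractors3, 5.0)
        assert st.hop_count == 0
        assert st.occupancy["basin_B"] == pytest.approx(1.0)
        assert st.occupancy["basin_A"] == pytest.approx(0.0)

    def test_debounce_filters_chatter(self):
        # label series alternating every step is chatter, not hopping
        labels = np.array([0, 1] * 500, dtype=np.int8)
        runs = _debounced_runs(labels, dt=0.01, debounce=0.1)
        assert len(runs) == 1

    def test_genuine_switch_counts_once(self):
        labels = np.array([0] * 400 + [1] * 600, dtype=np.int8)
        runs = _debounced_runs(labels, dt=0.01, debounce=0.1)
        assert [lab for lab, _ in runs] == [0, 1]
        assert runs[0][1] == pytest.approx(4.0)

    def test_short_trajectory_warns(self, params3, separatrix3, attractors3,
                                    stable3):
        traj = sw.simulate(params3, sw.NoiseSpec(0, 0), stable3[0].location,
                           1.0, h=1e-3, seed=0)
        st = sw.transition_stats(traj, separatrix3, attractors3, 10.0)
        assert st.warning is not None
        assert st.hop_count == 0


class TestExtinction:
    def test_extinction_time_detection(self, params3, stable3):
        traj = sw.simulate(params3, sw.NoiseSpec(0, 0), stable3[0].location,
                           10.0, h=1e-3, seed=0)
        assert extinction_time(traj) is None
        # consistency with the definition on a strongly forced path
        crash = sw.simulate(params3, sw.NoiseSpec(2.5, 2.5), (0.005, 0.005),
                            300.0, h=1e-3, seed=3)
        both = np.nonzero((crash.x < 1e-3) & (crash.y < 1e-3))[0]
        if len(both):
            assert extinction_time(crash) == pytest.approx(crash.t[both[0]])
        else:
            assert extinction_time(crash) is None
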