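"""Unit and property tests for the deposition simulator."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

import plateletabc as pa
from plateletabc.simulator import (
    DepositionParams,
    DeviceConfig,
    _advance_positions,
    cluster_statistics,
    initial_state,
    step_deposition,
    step_transport,
)

ZERO_DEP = dict(adhesion_rate=0.0, aggregation_rate=0.0, top_rate=0.0, albumin_rate=0.0,
                albumin_attenuation=0.0)


def small_config(**kw):
    defaults = dict(scale=0.05, dt=0.05)
    defaults.update(kw)
    return DeviceConfig(**defaults)


class TestTypes:
    def test_params_reject_negative_values(self):
        with pytest.raises(ValueError):
            DepositionParams(-1.0, 1, 1, 1e-3, 1e-4, 1e-3, 1e-3)

    def test_params_array_round_trip(self):
        p = DepositionParams(0.5, 1.0, 0.2, 3e-3, 3e-4, 1.5e-3, 6e-4)
        assert DepositionParams.from_array(p.as_array()) == p

    @pytest.mark.parametrize(
        "kw",
        [
            {"dt": 0.0},
            {"connectivity": 6},
            {"obs_times": (300.0, 20.0)},
            {"obs_times": (0.0, 400.0)},
            {"scale": -0.1},
        ],
    )
    def test_config_validation(self, kw):
        with pytest.raises(ValueError):
            DeviceConfig(**kw)

    def test_series_rejects_ragged_arrays(self):
        with pytest.raises(ValueError):
            pa.DepositionTimeSeries(times=[0, 20], n_clusters=[0], mean_cluster_size=[0, 0],
                                    n_platelet=[1, 1])


class TestTransport:
    def test_zero_speed_is_identity(self):
        cfg = small_config(shear_rate=0.0)
        p = DepositionParams(velocity_ap=0.0, velocity_nap=0.0, **ZERO_DEP)
        rng = np.random.default_rng(0)
        st_ = initial_state(cfg, rng)
        before = st_.positions.copy()
        step_transport(st_, p, cfg)
        np.testing.assert_array_equal(st_.positions, before)

    def test_bounce_back_mirror(self):
        """A forced upward jump of 2*delta from height-delta lands back at
        height-delta (mirror reflection at the top wall)."""
        height, width, dt = 820.0, 100.0, 0.05
        delta = 5.0
        pos = np.array([[50.0, 50.0, height - delta]])
        v = 2 * delta / dt  # radial = v*|s|*dt = 2*delta with |s| = 1
        out, trapped = _advance_positions(
            pos, np.array([v]), 0.0, height, width, dt, None,
            s=np.array([1.0]), lam=np.array([1]), r=np.array([0.0]),
        )
        assert not trapped.any()
        assert out[0, 2] == pytest.approx(height - delta)

    def test_msd_matches_vsquared_dt_t(self):
        """Mean-square vertical displacement of free walkers is v^2*dt*t
        (each step contributes variance v^2*dt^2 since E|s|^2 = 1)."""
        n, steps, dt, v = 10_000, 100, 0.05, 1000.0  # um/s
        rng = np.random.default_rng(12)
        height, width = 1e9, 1e9  # no boundary contact
        pos = np.full((n, 3), 5e8)
        z0 = pos[:, 2].copy()
        for _ in range(steps):
            pos, trapped = _advance_positions(
                pos, np.full(n, v), 0.0, height, width, dt, rng
            )
            assert not trapped.any()
        disp = pos[:, 2] - z0
        assert abs(disp.mean()) < 5 * v * dt * np.sqrt(steps / n)
        msd = np.mean(disp**2)
        assert msd == pytest.approx(v**2 * dt**2 * steps, rel=0.05)

    def test_trapped_leave_bulk_and_conservation_holds(self):
        cfg = small_config()
        p = DepositionParams(velocity_ap=2e-3, velocity_nap=1e-3, **ZERO_DEP)
        rng = np.random.default_rng(5)
        st_ = initial_state(cfg, rng)
        for _ in range(200):
            step_transport(st_, p, cfg)
            st_.check_conservation()
        assert st_.trapped_ap.sum() + st_.trapped_nap.sum() > 0
        assert np.all(st_.positions[:, 2] >= 0)
        assert np.all(st_.positions[:, 2] <= cfg.height)

    def test_nonfinite_position_raises(self):
        pos = np.array([[0.0, 0.0, np.inf]])
        with pytest.raises(FloatingPointError, match="index 0"):
            _advance_positions(pos, np.array([1.0]), 0.0, 10.0, 10.0, 0.1,
                               np.random.default_rng(0))

    def test_diffusion_limit_against_increment_resampling_oracle(self):
        """With zero shear, the z-marginal after many steps matches a
        brute-force resampling of the same increment distribution with
        reflection/absorption applied identically (two-sample KS)."""
        from scipy.stats import ks_2samp

        rng = np.random.default_rng(77)
        n, steps, dt, v, height = 3000, 80, 0.05, 2000.0, 820.0
        pos = np.empty((n, 3))
        pos[:, :2] = 500.0
        pos[:, 2] = rng.random(n) * height

        # oracle: independent per-particle loop with freshly drawn normal
        # increments (lam*|s| is exactly standard normal)
        z_oracle = rng.random(n) * height
        alive_o = np.ones(n, dtype=bool)
        for _ in range(steps):
            inc = rng.standard_normal(n) * v * dt
            z_oracle[alive_o] += inc[alive_o]
            over = alive_o & (z_oracle > height)
            z_oracle[over] = 2 * height - z_oracle[over]
            alive_o &= z_oracle > 0

        alive_mask = np.ones(n, dtype=bool)
        for _ in range(steps):
            pos, trapped = _advance_positions(
                pos, np.full(len(pos), v), 0.0, height, 1000.0, dt, rng
            )
            if trapped.any():
                pos = pos[~trapped]
        res = ks_2samp(pos[:, 2], z_oracle[alive_o])
        assert res.pvalue > 0.01


class TestDeposition:
    def _state(self, cfg, rng=None):
        return initial_state(cfg, rng or np.random.default_rng(0))

    def test_albumin_noop_at_saturation(self):
        cfg = small_config()
        st_ = self._state(cfg)
        st_.rho_al[:] = cfg.rho_max
        p = DepositionParams(0, 0, 0, albumin_rate=5e-3, albumin_attenuation=0,
                             velocity_ap=0, velocity_nap=0)
        step_deposition(st_, p, cfg)
        np.testing.assert_array_equal(st_.rho_al, cfg.rho_max)

    def test_adhesion_probability_without_attenuation(self):
        """With a_T = 0 a single trapped AP deposits with probability
        exactly adhesion_rate*dt (checked by exhaustive Monte Carlo)."""
        cfg = small_config(init_ap=0, init_nap=1e4)
        p = DepositionParams(adhesion_rate=2.0, aggregation_rate=0, top_rate=0,
                             albumin_rate=0, albumin_attenuation=0,
                             velocity_ap=0, velocity_nap=0)
        rng = np.random.default_rng(3)
        hits = 0
        n_rep = 4000
        for _ in range(n_rep):
            st_ = self._state(cfg, rng)
            st_.trapped_ap[0, 0] = 1
            st_.init_ap = 1
            step_deposition(st_, p, cfg)
            hits += st_.deposited_ap
        assert hits / n_rep == pytest.approx(p.adhesion_rate * cfg.dt, rel=0.1)

    def test_albumin_follows_closed_form_saturation(self):
        """Euler track of the mean-field albumin density stays within 1% of
        rho_max*(1 - exp(-p_F t)) when p_F*dt <= 1e-2."""
        cfg = small_config(dt=0.01)
        p = DepositionParams(0, 0, 0, albumin_rate=1.0, albumin_attenuation=0,
                             velocity_ap=0, velocity_nap=0)
        st_ = self._state(cfg)
        for k in range(1, 501):
            step_deposition(st_, p, cfg)
            t = k * cfg.dt
            exact = cfg.rho_max * (1 - np.exp(-p.albumin_rate * t))
            assert st_.rho_al[0, 0] == pytest.approx(exact, rel=0.01)

    def test_albumin_monotone_and_bounded(self):
        cfg = small_config()
        p = DepositionParams(0.5, 1.0, 0.2, 3e-3, 3e-4, 1e-3, 5e-4)
        st_ = self._state(cfg)
        prev = st_.rho_al.copy()
        for _ in range(300):
            step_transport(st_, p, cfg)
            step_deposition(st_, p, cfg)
            assert np.all(st_.rho_al >= prev - 1e-12)
            assert np.all(st_.rho_al <= cfg.rho_max + 1e-9)
            prev = st_.rho_al.copy()

    def test_deposition_conserves_platelets_and_grows_monotonically(self):
        cfg = small_config()
        p = DepositionParams(0.5, 1.0, 0.2, 3e-3, 3e-4, 2e-3, 1e-3)
        st_ = self._state(cfg)
        prev_dep = 0
        prev_occ = 0
        for _ in range(400):
            step_transport(st_, p, cfg)
            step_deposition(st_, p, cfg)
            st_.check_conservation()
            dep = st_.deposited_ap + st_.deposited_nap
            occ = int((st_.substrate > 0).sum())
            assert dep >= prev_dep
            assert occ >= prev_occ
            prev_dep, prev_occ = dep, occ


def brute_force_clusters(grid: np.ndarray, connectivity: int, periodic: bool = True):
    """Flood-fill oracle for cluster statistics."""
    ny, nx = grid.shape
    occ = grid > 0
    seen = np.zeros_like(occ)
    if connectivity == 4:
        offsets = [(0, 1), (0, -1), (1, 0), (-1, 0)]
    else:
        offsets = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    sizes = []
    for i in range(ny):
        for j in range(nx):
            if occ[i, j] and not seen[i, j]:
                stack = [(i, j)]
                seen[i, j] = True
                size = 0
                while stack:
                    y, x = stack.pop()
                    size += 1
                    for dy, dx in offsets:
                        yy, xx = y + dy, x + dx
                        if periodic:
                            yy %= ny
                            xx %= nx
                        elif not (0 <= yy < ny and 0 <= xx < nx):
                            continue
                        if occ[yy, xx] and not seen[yy, xx]:
                            seen[yy, xx] = True
                            stack.append((yy, xx))
                sizes.append(size)
    return len(sizes), (float(np.mean(sizes)) if sizes else 0.0)


class TestClusterStatistics:
    def test_empty_substrate_is_zero_zero(self):
        cfg = small_config()
        ny, nx = cfg.grid_shape[::-1]
        assert cluster_statistics(np.zeros((ny, nx), int), cfg) == (0.0, 0.0)

    def test_full_substrate_is_one_cluster(self):
        cfg = small_config()
        ny, nx = cfg.grid_shape[::-1]
        n, s = cluster_statistics(np.ones((ny, nx), int), cfg)
        assert n == pytest.approx(1.0 / cfg.substrate_area_mm2)
        assert s == ny * nx

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle_on_random_grids(self, connectivity):
        cfg = DeviceConfig(scale=50 * np.sqrt(5.0) / 1000.0, connectivity=connectivity)
        assert cfg.grid_shape == (50, 50)
        rng = np.random.default_rng(99)
        for _ in range(100):
            grid = (rng.random((50, 50)) < rng.uniform(0.05, 0.6)).astype(int)
            n, s = cluster_statistics(grid, cfg)
            n_oracle, s_oracle = brute_force_clusters(grid, connectivity)
            assert round(n * cfg.substrate_area_mm2) == n_oracle
            if n_oracle:
                assert s == pytest.approx(s_oracle)

    def test_periodic_wrap_merges_edge_clusters(self):
        cfg = small_config(connectivity=4)
        ny, nx = cfg.grid_shape[::-1]
        grid = np.zeros((ny, nx), int)
        grid[0, 3] = 1
        grid[ny - 1, 3] = 1  # touching across the periodic seam
        n, s = cluster_statistics(grid, cfg)
        assert round(n * cfg.substrate_area_mm2) == 1
        assert s == 2.0


class TestSimulate:
    def test_no_deposition_channels_means_no_clusters(self, fast_config):
        p = DepositionParams(0, 0, 0, albumin_rate=3e-3, albumin_attenuation=3e-4,
                             velocity_ap=2e-3, velocity_nap=1e-3)
        ts = pa.simulate(p, fast_config, seed=1)
        assert np.all(ts.n_clusters == 0)
        assert np.all(ts.mean_cluster_size == 0)
        assert np.all(ts.n_platelet == ts.n_platelet[0])

    def test_no_ap_means_no_clusters(self):
        cfg = small_config(init_ap=0.0)
        p = DepositionParams(0.5, 2.0, 0.2, 3e-3, 3e-4, 2e-3, 1e-3)
        ts = pa.simulate(p, cfg, seed=1)
        assert np.all(ts.n_clusters == 0)

    @pytest.mark.parametrize("engine", ["fast", "reference"])
    def test_seeded_determinism(self, engine):
        cfg = small_config(end_time=60.0, obs_times=(0.0, 20.0, 60.0))
        p = DepositionParams(0.5, 1.0, 0.2, 3e-3, 3e-4, 2e-3, 1e-3)
        a = pa.simulate(p, cfg, seed=9, engine=engine)
        b = pa.simulate(p, cfg, seed=9, engine=engine)
        assert a == b

    def test_zero_particles_raises_with_advice(self):
        cfg = small_config(scale=1e-4)
        p = DepositionParams(0.5, 1.0, 0.2, 3e-3, 3e-4, 2e-3, 1e-3)
        with pytest.raises(ValueError, match="scale"):
            pa.simulate(p, cfg, seed=0)

    def test_non_multiple_end_time_warns(self):
        cfg = small_config(dt=0.07, end_time=1.0, obs_times=(0.0, 1.0))
        p = DepositionParams(0, 0, 0, 0, 0, 1e-3, 1e-3)
        with pytest.warns(RuntimeWarning, match="not a multiple"):
            pa.simulate(p, cfg, seed=0)

    def test_rate_clamping_warns(self):
        cfg = small_config()
        p = DepositionParams(100.0, 0, 0, 0, 0, 1e-3, 1e-3)
        with pytest.warns(RuntimeWarning, match="clamped"):
            pa.simulate(p, cfg, seed=0)

    def test_engines_agree_in_distribution(self):
        """Fast (blocked-transport) and reference engines produce the same
        observable distributions (Welch t-test on every coordinate)."""
        from scipy.stats import ttest_ind

        cfg = small_config(end_time=120.0, obs_times=(0.0, 20.0, 120.0))
        p = DepositionParams(0.5, 1.0, 0.2, 3e-3, 3e-4, 1.5e-3, 6e-4)
        f = np.vstack([pa.simulate(p, cfg, seed=s, engine="fast").as_vector()
                       for s in range(25)])
        r = np.vstack([pa.simulate(p, cfg, seed=1000 + s, engine="reference").as_vector()
                       for s in range(25)])
        for j in range(f.shape[1]):
            if f[:, j].std() + r[:, j].std() > 0:
                assert ttest_ind(f[:, j], r[:, j]).pvalue > 0.001

    def test_scale_invariance_of_per_area_observables(self):
        """Doubling the window scale (4x area and particles) leaves the
        mean cluster density per mm^2 unchanged within Monte-Carlo error."""
        p = DepositionParams(0.5, 1.0, 0.2, 3e-3, 3e-4, 1.5e-3, 6e-4)
        cfg_s = small_config(end_time=120.0, obs_times=(0.0, 120.0))
        cfg_l = small_config(scale=0.1, end_time=120.0, obs_times=(0.0, 120.0))
        small = np.array([pa.simulate(p, cfg_s, seed=s).n_clusters[-1] for s in range(12)])
        large = np.array([pa.simulate(p, cfg_l, seed=100 + s).n_clusters[-1] for s in range(12)])
        sem = np.sqrt(small.var() / 12 + large.var() / 12)
        assert abs(small.mean() - large.mean()) < 4 * sem + 1e-9


class TestRateRatioInvariant:
    @given(
        agg=st.floats(0.1, 10.0),
        adh=st.floats(0.1, 10.0),
        rho=st.floats(0.0, 1e5),
        a_t=st.floats(0.0, 1e-3),
    )
    def test_aggregation_adhesion_ratio_shares_attenuation(self, agg, adh, rho, a_t):
        """Adhesion and aggregation probabilities share the albumin
        attenuation factor, so their ratio equals the rate ratio wherever
        neither probability clamps."""
        from plateletabc.simulator import _clamped_prob

        dt = 1e-4  # small enough that no clamping occurs
        atten = np.exp(-a_t * np.array([rho]))
        q = _clamped_prob(adh, dt, atten)
        r = _clamped_prob(agg, dt, atten)
        if q[0] > 0:
            assert r[0] / q[0] == pytest.approx(agg / adh, rel=1e-9)

    def test_negative_probability_is_an_error(self):
        from plateletabc.simulator import _clamped_prob

        with pytest.raises(ValueError):
            _clamped_prob(-1.0, 0.1)
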