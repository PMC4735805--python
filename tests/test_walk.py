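"""Lattice binding walk: conservation, diffusion, exact-chain agreement, Kd."""

import numpy as np
import pytest

from idisc.walk import (
    KdEstimate,
    WalkConfig,
    calibrate_probabilities,
    compare_arrangements,
    estimate_kd,
    init_state,
    n_ligate_from_concentration,
    run_walk,
    step_walk,
)

from markov_oracle import expected_bound_count


def tiny_config(**kw):
    base = dict(
        nx=3, ny=3, nz=3, n_ligate=2, n_channels=1,
        p_bind=0.3, p_unbind=0.2, attraction=2.0,
        arrangement="distributed", n_steps=100, seed=0,
    )
    base.update(kw)
    return WalkConfig(**base)


class TestConfig:
    def test_default_lattice_from_physical_sizes(self):
        cfg = WalkConfig()
        assert (cfg.nx, cfg.ny, cfg.nz) == (32, 32, 16)  # round(1066/33) = 32
        assert cfg.n_ligate == 2127 and cfg.n_channels == 44
        assert cfg.n_steps == 500 and cfg.n_reps == 1000

    def test_ligate_count_matches_unit_conversion(self):
        assert n_ligate_from_concentration(6.0, WalkConfig()) == 2127

    def test_invalid_probabilities(self):
        with pytest.raises(ValueError):
            WalkConfig(p_bind=1.5)
        with pytest.raises(ValueError):
            WalkConfig(attraction=0.5)
        with pytest.raises(ValueError):
            WalkConfig(nx=4, ny=4, n_channels=44)


class TestInitState:
    def test_distributed_min_spacing(self):
        st = init_state(WalkConfig(arrangement="distributed"))
        xy = st.channel_xy
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1).astype(float)
        np.fill_diagonal(d2, np.inf)
        assert np.sqrt(d2.min()) >= 4.0

    def test_clustered_bounding_box(self):
        st = init_state(WalkConfig(arrangement="clustered"))
        xy = st.channel_xy
        assert np.ptp(xy[:, 0]) <= 6 and np.ptp(xy[:, 1]) <= 6  # within 7x7 sites

    def test_same_seed_identical(self):
        a = init_state(tiny_config())
        b = init_state(tiny_config())
        assert np.array_equal(a.positions, b.positions)

    def test_ligates_start_off_channel_face(self):
        st = init_state(WalkConfig())
        assert (st.positions[:, 2] >= 1).all()


class TestStepDynamics:
    def test_no_binding_when_p_bind_zero(self):
        cfg = tiny_config(p_bind=0.0, n_steps=200)
        trace, _ = run_walk(cfg)
        assert (trace == 0).all()

    def test_absorbing_binding_saturates(self):
        cfg = tiny_config(
            nx=4, ny=4, nz=3, n_ligate=6, n_channels=4,
            p_bind=1.0, p_unbind=0.0, n_steps=400, attraction=4.0,
        )
        trace, _ = run_walk(cfg)
        assert (np.diff(trace) >= 0).all()
        assert trace[-1] == min(cfg.n_channels, cfg.n_ligate)

    def test_particle_conservation_and_domain(self):
        cfg = tiny_config(n_ligate=5, n_steps=50)
        rng = np.random.default_rng(1)
        st = init_state(cfg, rng)
        for _ in range(50):
            step_walk(st, cfg, rng)
            assert len(st.positions) == 5
            assert (st.positions >= 0).all()
            assert (st.positions < [cfg.nx, cfg.ny, cfg.nz]).all()
            assert st.n_bound <= cfg.n_channels
            # occupancy table consistent with per-ligate bound state
            for ci, li in enumerate(st.channel_occupant):
                if li >= 0:
                    assert st.bound_to[li] == ci

    def test_msd_linear_in_time(self):
        """Free 6-neighbour lattice diffusion: MSD(t) = t * step^2 within 5%."""
        cfg = WalkConfig(
            nx=41, ny=41, nz=41, n_ligate=800, n_channels=0,
            p_bind=0.0, p_unbind=0.0, attraction=1.0, n_steps=25,
        )
        rng = np.random.default_rng(8)
        st = init_state(cfg, rng)
        # start everything at the center so boundaries are out of reach
        st.positions[:] = [20, 20, 20]
        start = st.positions.copy()
        t = 25
        for _ in range(t):
            step_walk(st, cfg, rng)
        msd = ((st.positions - start) ** 2).sum(axis=1).mean()
        assert msd == pytest.approx(t, rel=0.05)

    def test_deterministic_under_seed(self):
        a, _ = run_walk(tiny_config(n_steps=150), seed=5)
        b, _ = run_walk(tiny_config(n_steps=150), seed=5)
        assert np.array_equal(a, b)


class TestExactChainAgreement:
    def test_stationary_bound_count_matches_enumeration(self):
        """Long-run mean bound count on a 3x3x3 lattice with 2 ligates and
        1 channel agrees with the exact stationary distribution of the
        enumerated Markov chain."""
        cfg = tiny_config(p_bind=0.3, p_unbind=0.2, attraction=2.0, n_steps=3000)
        exact = expected_bound_count(3, (1, 1, 0), 0.3, 0.2, 2.0)
        means = []
        for seed in range(12):
            trace, _ = run_walk(cfg, seed=100 + seed)
            means.append(trace[1000:].mean())
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - exact) <= 4 * max(se, 1e-3)

    def test_kd_matches_exact_stationary_value(self):
        """Kd read out from simulated traces is within 10% of the value
        implied by the exact chain's stationary occupancy."""
        cfg = tiny_config(p_bind=0.8, p_unbind=0.1, attraction=2.0, n_steps=6000)
        exact_b = expected_bound_count(3, (1, 1, 0), 0.8, 0.1, 2.0)
        kd_exact = (
            cfg.concentration_nM(cfg.n_ligate - exact_b)
            * (cfg.n_channels - exact_b)
            / exact_b
        )
        pooled = []
        for seed in range(16):
            trace, _ = run_walk(cfg, seed=seed)
            pooled.append(trace[2000:].mean())
        b = np.mean(pooled)
        kd_sim = cfg.concentration_nM(cfg.n_ligate - b) * (cfg.n_channels - b) / b
        assert kd_sim == pytest.approx(kd_exact, rel=0.10)


class TestKdEstimate:
    cfg = WalkConfig()

    def test_half_occupancy_identity(self):
        """At half channel occupancy Kd equals the free-ligate concentration."""
        half = self.cfg.n_channels / 2
        trace = np.full(500, half)
        est = estimate_kd(trace, self.cfg)
        assert est.kd_nM == pytest.approx(self.cfg.concentration_nM(self.cfg.n_ligate - half))

    def test_zero_binding_flagged_infinite(self):
        est = estimate_kd(np.zeros(500), self.cfg)
        assert est.infinite and np.isinf(est.kd_nM)

    def test_window_covers_last_40_percent(self):
        est = estimate_kd(np.ones(500), self.cfg)
        assert est.window == (300, 500)

    def test_nonstationary_flagged(self):
        est = estimate_kd(np.arange(500, dtype=float), self.cfg)
        assert not est.stationary


class TestCalibration:
    small = dict(
        nx=12, ny=12, nz=8, n_ligate=120, n_channels=9,
        attraction=4.0, n_steps=300, arrangement="clustered",
    )

    def test_zero_bind_rows_flagged_infinite(self):
        cfg = WalkConfig(**self.small)
        df = calibrate_probabilities(
            100.0, [(0.0, 0.01), (0.5, 0.01)], cfg, n_reps=2, seed=1
        )
        assert df.loc[df.p_bind == 0.0, "infinite"].all()
        assert not df.loc[df.p_bind == 0.5, "infinite"].any()

    def test_kd_increases_with_unbinding_rate(self):
        """At fixed p_bind the estimated Kd trends upward in p_unbind."""
        cfg = WalkConfig(**self.small)
        grid = [(0.5, pu) for pu in (0.002, 0.01, 0.05)]
        df = calibrate_probabilities(100.0, grid, cfg, n_reps=6, seed=2)
        df = df.sort_values("p_unbind")
        kds = df["kd_nM"].to_numpy()
        assert kds[0] < kds[-1]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            calibrate_probabilities(100.0, [], WalkConfig(**self.small))

    def test_all_infinite_is_calibration_failure(self):
        cfg = WalkConfig(**self.small)
        with pytest.raises(RuntimeError):
            calibrate_probabilities(100.0, [(0.0, 0.01)], cfg, n_reps=2)


def test_compare_arrangements_structure():
    cfg = WalkConfig(
        nx=12, ny=12, nz=8, n_ligate=120, n_channels=9,
        p_bind=0.5, p_unbind=0.01, attraction=4.0, n_steps=200,
    )
    out = compare_arrangements(cfg, n_reps=6, seed=4)
    assert len(out["clustered_per_rep"]) == 6
    assert out["n_reps"] == 6
    assert np.isfinite(out["clustered_kd_nM"]) and np.isfinite(out["distributed_kd_nM"])
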