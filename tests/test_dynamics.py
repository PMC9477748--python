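"""MSD computation, diffusion fitting, mobility and oligomer metrics."""

import numpy as np
import pytest

from dimertrack import (
    AffineTransform2D,
    SimulationConfig,
    Trajectory,
    analyze_cell,
    compute_msd,
    fit_diffusion,
    mobility_fractions,
    oligomer_fraction,
    pool_msd,
    simulate_cell,
)
from dimertrack.dynamics import MsdCurve, per_trajectory_diffusion
from dimertrack.errors import AnalysisError

from conftest import noiseless_overrides

DT = 0.032


def brownian_tracks(n, d_um2_s, sigma_nm, n_frames=150, seed=0):
    rng = np.random.default_rng(seed)
    step = np.sqrt(2 * d_um2_s * 1e6 * DT)
    out = []
    for i in range(n):
        true = np.cumsum(rng.standard_normal((n_frames, 2)) * step, axis=0)
        obs = true + rng.standard_normal((n_frames, 2)) * sigma_nm
        out.append(Trajectory(i, "A", np.arange(n_frames), obs))
    return out


class TestComputeMsd:
    def test_constant_position_zero_msd(self):
        t = Trajectory(0, "A", np.arange(30), np.tile([5.0, 5.0], (30, 1)))
        assert np.all(compute_msd(t).msd == 0.0)

    def test_ballistic_closed_form(self):
        xy = np.array([[0.0, 0.0], [100.0, 0.0], [200.0, 0.0], [300.0, 0.0]])
        curve = compute_msd(Trajectory(0, "A", np.arange(4), xy))
        assert curve.lags.tolist() == [1, 2, 3]
        assert curve.msd.tolist() == [1e4, 4e4, 9e4]
        assert curve.counts.tolist() == [3, 2, 1]

    def test_gap_frames_contribute_no_pairs(self):
        t = Trajectory(0, "A", np.array([0, 1, 3]), np.zeros((3, 2)))
        curve = compute_msd(t)
        assert curve.lags.tolist() == [1, 2, 3]
        assert curve.counts.tolist() == [1, 1, 1]

    def test_single_point_rejected(self):
        with pytest.raises(AnalysisError):
            compute_msd(Trajectory(0, "A", [0], [[0.0, 0.0]]))

    def test_pooled_brownian_msd_is_linear(self):
        tracks = brownian_tracks(1000, 0.1, 0.0, n_frames=30, seed=5)
        est = fit_diffusion(pool_msd([compute_msd(t) for t in tracks]), (1, 2, 3, 4, 5), DT)
        assert est.r_squared > 0.99


class TestFitDiffusion:
    def test_exact_line_inverts_to_d(self):
        lags = np.arange(1, 6)
        msd = 4 * 0.1 * lags * DT * 1e6  # nm²
        est = fit_diffusion(MsdCurve(lags, msd, np.full(5, 100)), (1, 2, 3, 4, 5), DT)
        assert est.d_um2_s == pytest.approx(0.100, abs=1e-12)
        assert est.loc_error_sigma_nm == pytest.approx(0.0, abs=1e-6)

    def test_intercept_recovered_as_localization_error(self):
        lags = np.arange(1, 6)
        msd = 4 * 0.1 * lags * DT * 1e6 + 4 * 15.0**2
        est = fit_diffusion(MsdCurve(lags, msd, np.full(5, 100)), (1, 2, 3, 4, 5), DT)
        assert est.d_um2_s == pytest.approx(0.100, abs=1e-12)
        assert est.loc_error_sigma_nm == pytest.approx(15.0, abs=1e-9)

    def test_negative_slope_truncated_and_flagged(self):
        lags = np.arange(1, 6)
        msd = 1000.0 - 10.0 * lags
        est = fit_diffusion(MsdCurve(lags, msd, np.full(5, 10)), (1, 2, 3, 4, 5), DT)
        assert est.d_um2_s == 0.0
        assert est.negative_slope

    def test_missing_fit_lag_rejected(self):
        curve = MsdCurve(np.array([1, 2]), np.array([1.0, 2.0]), np.array([5, 4]))
        with pytest.raises(AnalysisError):
            fit_diffusion(curve, (1, 2, 3), DT)

    @pytest.mark.parametrize("d_true", [0.01, 0.05, 0.2])
    def test_unbiased_across_diffusion_range(self, d_true):
        tracks = brownian_tracks(150, d_true, 15.0, seed=int(d_true * 1000))
        est = fit_diffusion(pool_msd([compute_msd(t) for t in tracks]), (1, 2, 3, 4, 5), DT)
        assert est.d_um2_s == pytest.approx(d_true, rel=0.10)


class TestMobility:
    def test_all_static_tracks_fully_immobile(self):
        tracks = [
            Trajectory(i, "A", np.arange(20), np.tile([i * 100.0, 0.0], (20, 1)))
            for i in range(10)
        ]
        frac, ds = mobility_fractions(tracks, DT)
        assert frac == 1.0
        assert len(ds) == 10

    def test_fast_brownian_rarely_called_immobile(self):
        tracks = brownian_tracks(200, 0.1, 15.0, seed=8)
        frac, _ = mobility_fractions(tracks, DT)
        assert frac <= 0.05

    def test_thirty_percent_immobile_recovered(self):
        mobile = brownian_tracks(140, 0.1, 15.0, seed=9)
        immobile = [
            Trajectory(1000 + i, "A", np.arange(150),
                       np.random.default_rng(i).standard_normal((150, 2)) * 18.0)
            for i in range(60)
        ]
        frac, _ = mobility_fractions(mobile + immobile, DT)
        assert frac == pytest.approx(0.30, abs=0.05)

    def test_no_qualifying_tracks_gives_missing(self):
        short = [Trajectory(0, "A", np.arange(5), np.zeros((5, 2)))]
        frac, ds = mobility_fractions(short, DT)
        assert frac is None and len(ds) == 0

    def test_per_trajectory_d_cancels_localization_offset(self):
        tracks = brownian_tracks(300, 0.08, 25.0, seed=10)
        ds = [per_trajectory_diffusion(t, DT) for t in tracks]
        assert np.mean(ds) == pytest.approx(0.08, rel=0.1)


class TestOligomerFraction:
    def _dimer(self, a_int, b_int, n=15):
        import pandas as pd

        from dimertrack import CoTrajectory

        rec = pd.DataFrame(
            {
                "frame": np.arange(n), "a_x_nm": 0.0, "a_y_nm": 0.0,
                "b_x_nm": 0.0, "b_y_nm": 10.0, "separation_nm": 10.0,
                "mid_x_nm": 0.0, "mid_y_nm": 5.0,
                "a_intensity": float(a_int), "b_intensity": float(b_int),
                "a_traj": 0, "b_traj": 0,
            }
        )
        return CoTrajectory(0, rec)

    def test_monomeric_intensities_give_zero(self):
        dimers = [self._dimer(1000, 1000) for _ in range(5)]
        assert oligomer_fraction(dimers, 1000.0, 1000.0) == 0.0

    def test_doubled_intensity_gives_one(self):
        dimers = [self._dimer(2000, 2000) for _ in range(5)]
        assert oligomer_fraction(dimers, 1000.0, 1000.0) == 1.0

    def test_either_channel_sufficient(self):
        dimers = [self._dimer(1000, 2000), self._dimer(1000, 1000)]
        assert oligomer_fraction(dimers, 1000.0, 1000.0) == 0.5

    def test_missing_without_dimers_or_reference(self):
        assert oligomer_fraction([], 1000.0, 1000.0) is None
        assert oligomer_fraction([self._dimer(1, 1)], None, 1000.0) is None


def test_dimers_diffuse_slower_than_monomers():
    # D_dimer < D_free must show up as a slower pooled co-trajectory MSD
    cfg = SimulationConfig(
        seed=77, density=0.25,
        complex_mix={"monomer_a": 0.25, "monomer_b": 0.25, "heterodimer_ab": 0.5},
        d_free=0.15, d_dimer=0.05, immobile_fraction=0.0,
        **noiseless_overrides(),
    )
    sim = simulate_cell(cfg)
    res, inter = analyze_cell(
        sim["locs_a"], sim["locs_b"], AffineTransform2D.identity(), seed=77
    )
    dimers = inter["dimers"]
    coloc_a = {tid for c in inter["cotrajectories"] for tid in c.a_traj_ids}
    free = [
        t for t in inter["mobile"]["A"]
        if t.trajectory_id not in coloc_a and t.lifetime > 10
    ]
    d_free = fit_diffusion(pool_msd([compute_msd(t) for t in free]), (1, 2, 3, 4, 5), DT)
    co_tracks = [
        Trajectory(c.cotraj_id, "M", c.frames, c.midpoints())
        for c in dimers if c.n_matched > 10
    ]
    d_dimer = fit_diffusion(
        pool_msd([compute_msd(t) for t in co_tracks]), (1, 2, 3, 4, 5), DT
    )
    assert d_dimer.d_um2_s < d_free.d_um2_s
    assert d_dimer.d_um2_s == pytest.approx(0.05, rel=0.25)
    assert d_free.d_um2_s == pytest.approx(0.15, rel=0.25)
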