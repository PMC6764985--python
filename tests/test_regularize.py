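import numpy as np
import pandas as pd
import pytest

from _oracles import dcrw_joint_gaussian_smoother
from whalemove.geodesy import great_circle_km
from whalemove.params import SexLabel
from whalemove.regularize import (
    _run_filter,
    _prepare_segment,
    _smooth_segment,
    draw_realizations,
    fit_ssm,
    split_on_gaps,
)
from whalemove.simulate import degrade_to_argos, simulate_track


def _sim_obs(n_steps=200, seed=1, **kw):
    path = simulate_track("w1", SexLabel.female, n_steps=n_steps, seed=seed, start_lonlat=(100, -50))
    obs = degrade_to_argos(path, seed=seed + 1, **kw)
    return path, obs


class TestGridAndValidation:
    def test_output_grid_exactly_six_hourly(self):
        _, obs = _sim_obs()
        fit = fit_ssm(obs)
        track = fit.track
        dt = np.diff(track.times.asi8) / 3.6e12
        np.testing.assert_allclose(dt, 6.0)
        # four estimates per calendar day once the first day is complete
        counts = pd.Series(1, index=track.times).groupby(track.times.date).sum()
        assert (counts.iloc[1:-1] == 4).all()

    def test_too_few_observations_rejected(self):
        _, obs = _sim_obs()
        with pytest.raises(ValueError):
            fit_ssm(obs.iloc[:5])

    def test_gap_splitting(self):
        _, obs = _sim_obs(n_steps=120)
        mid = obs["date"].iloc[len(obs) // 2]
        gap = (obs["date"] < mid) | (obs["date"] > mid + pd.Timedelta(days=10))
        pieces = split_on_gaps(obs[gap], gap_split_days=7.0)
        assert len(pieces) == 2


class TestSmootherExactness:
    def test_noiseless_on_grid_observations_recovered(self):
        path, _ = _sim_obs(n_steps=60)
        # observe every node exactly, zero noise
        obs = pd.DataFrame(
            {
                "id": "w1",
                "date": path.times,
                "lc": "3",
                "lon": path.lonlat[:, 0],
                "lat": path.lonlat[:, 1],
            }
        )
        fit = fit_ssm(obs, error_sd_km={c: 0.0 for c in "3210AB"})
        track = fit.track
        idx = track.times.get_indexer(path.times)
        assert (idx >= 0).all()
        d = great_circle_km(
            track.lonlat[idx, 0], track.lonlat[idx, 1], path.lonlat[:, 0], path.lonlat[:, 1]
        )
        assert np.max(d) < 1e-6

    def test_five_node_joint_gaussian_oracle(self):
        # 5-node toy problem, 1-D check per axis against direct conditioning
        grid = np.array([0.0, 6.0, 12.0, 18.0, 24.0])
        obs_t = np.array([2.0, 7.5, 11.0, 16.0, 21.5, 24.0])
        rng = np.random.default_rng(3)
        obs_v = rng.normal(scale=20.0, size=obs_t.size)
        obs_var = np.full(obs_t.size, 4.0)
        gamma_c, sigma2 = 0.4, 9.0

        times = pd.Timestamp("2016-10-01", tz="UTC") + pd.to_timedelta(obs_t, unit="h")
        obs = pd.DataFrame(
            {"id": "t", "date": times, "lc": "2", "lon": 100.0, "lat": -50.0}
        )
        seg = _prepare_segment(obs, 6.0, {"2": 2.0})
        # overwrite planar coords with the 1-D toy values on the x axis
        seg.obs_xy = np.column_stack([obs_v, np.zeros_like(obs_v)])
        _run_filter(seg, gamma_c, sigma2, store=True)
        _smooth_segment(seg, gamma_c, sigma2)

        mean, var = dcrw_joint_gaussian_smoother(
            grid, obs_t, obs_v, obs_var, gamma_c, sigma2, prior_var=1.0e4
        )
        np.testing.assert_allclose(seg.m_smooth[:, 0], mean, atol=1e-8)
        np.testing.assert_allclose(seg.sd_smooth**2, var, atol=1e-8)

    def test_smoothing_reduces_rmse_vs_raw_class_b(self):
        path, obs = _sim_obs(
            n_steps=300,
            class_probs={"B": 1.0},
            error_sd_km={"B": 10.0},
            mean_gap_hours=2.0,
        )
        fit = fit_ssm(obs, error_sd_km={"B": 10.0})
        track = fit.track
        from whalemove.simulate import interpolate_path

        truth_at_obs = interpolate_path(path, pd.DatetimeIndex(obs["date"]))
        rmse_raw = np.sqrt(
            np.mean(
                great_circle_km(
                    obs["lon"].to_numpy(), obs["lat"].to_numpy(),
                    truth_at_obs[:, 0], truth_at_obs[:, 1],
                )
                ** 2
            )
        )
        common = track.times.intersection(path.times)
        i1 = track.times.get_indexer(common)
        i2 = path.times.get_indexer(common)
        rmse_sm = np.sqrt(
            np.mean(
                great_circle_km(
                    track.lonlat[i1, 0], track.lonlat[i1, 1],
                    path.lonlat[i2, 0], path.lonlat[i2, 1],
                )
                ** 2
            )
        )
        assert rmse_sm < rmse_raw

    def test_gamma_zero_process_recovered_within_3_se(self):
        # generate an uncorrelated random walk (gamma_c = 0) directly
        rng = np.random.default_rng(12)
        n = 500
        x = np.cumsum(rng.normal(scale=8.0, size=n))
        y = np.cumsum(rng.normal(scale=8.0, size=n))
        from whalemove.geodesy import AzimuthalEquidistant

        proj = AzimuthalEquidistant(100.0, -50.0)
        lon, lat = proj.inverse(x, y)
        times = pd.date_range("2016-10-01", periods=n, freq="6h", tz="UTC")
        obs = pd.DataFrame(
            {"id": "rw", "date": times, "lc": "1", "lon": lon, "lat": lat}
        )
        fit = fit_ssm(obs, error_sd_km={"1": 1.5})
        assert abs(fit.gamma_c) < 3 * fit.gamma_se


class TestRealizations:
    def test_reject_zero_draws_and_require_convergence(self):
        _, obs = _sim_obs(n_steps=80)
        fit = fit_ssm(obs)
        with pytest.raises(ValueError):
            draw_realizations(fit, 0)

    def test_fixed_seed_reproducible(self):
        _, obs = _sim_obs(n_steps=80)
        fit = fit_ssm(obs)
        a = draw_realizations(fit, 3, seed=5)
        b = draw_realizations(fit, 3, seed=5)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.lonlat, tb.lonlat)
        assert [t.realization for t in a] == [1, 2, 3]

    def test_tiny_variance_collapses_to_point_estimate(self):
        path, _ = _sim_obs(n_steps=60)
        obs = pd.DataFrame(
            {
                "id": "w1",
                "date": path.times,
                "lc": "3",
                "lon": path.lonlat[:, 0],
                "lat": path.lonlat[:, 1],
            }
        )
        fit = fit_ssm(obs, error_sd_km={"3": 1e-4})
        track = fit.track
        (real,) = draw_realizations(fit, 1, seed=1)
        d = great_circle_km(
            real.lonlat[:, 0], real.lonlat[:, 1], track.lonlat[:, 0], track.lonlat[:, 1]
        )
        assert np.max(d) < 0.05  # km

    def test_nominal_interval_coverage(self):
        # the 95% interval around smoothed positions should contain the true
        # path ~95% of the time, despite the DCRW being a single-regime
        # approximation to 2-state switching movement
        rng = np.random.default_rng(21)
        hits = total = 0
        for i in range(120):
            path = simulate_track(
                f"c{i}", SexLabel.unknown, n_steps=40, seed=rng, start_lonlat=(100, -50)
            )
            obs = degrade_to_argos(path, seed=rng)
            fit = fit_ssm(obs)
            track = fit.track
            proj = fit.segments[0].proj
            common = track.times.intersection(path.times)
            i1 = track.times.get_indexer(common)
            i2 = path.times.get_indexer(common)
            xt, yt = proj.forward(path.lonlat[i2, 0], path.lonlat[i2, 1])
            xs, ys = proj.forward(track.lonlat[i1, 0], track.lonlat[i1, 1])
            sd = track.pos_sd_km[i1]
            for est, tru in ((xs, xt), (ys, yt)):
                hits += np.sum(np.abs(est - tru) <= 1.959963984540054 * sd)
                total += len(sd)
        assert hits / total == pytest.approx(0.95, abs=0.03)

    def test_realization_spread_matches_smoother_sd(self):
        _, obs = _sim_obs(n_steps=120, class_probs={"B": 1.0}, error_sd_km={"B": 10.0})
        fit = fit_ssm(obs, error_sd_km={"B": 10.0})
        track = fit.track
        reals = draw_realizations(fit, 100, seed=2)
        proj = fit.segments[0].proj
        xs = np.stack([proj.forward(r.lonlat[:, 0], r.lonlat[:, 1])[0] for r in reals])
        sample_sd = xs.std(axis=0, ddof=1)
        # compare MC spread to the reported smoother SD, away from the edges
        inner = slice(5, -5)
        ratio = np.median(sample_sd[inner] / track.pos_sd_km[inner])
        assert ratio == pytest.approx(1.0, abs=0.15)
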