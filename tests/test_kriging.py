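"""Ordinary kriging, variogram fitting and sensor calibration."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from agrifuse import (
    CovariateSample,
    OrdinaryKriging,
    SensorReading,
    VariogramModel,
    calibrate_against_sensors,
    estimate_moisture_at_points,
    fit_variogram,
    krige,
)
from agrifuse.errors import (
    GeometryError,
    InsufficientDataError,
    MissingCovariateError,
    SensorKindError,
)
from agrifuse.kriging import empirical_variogram, local_xy

LAT0, LON0 = 37.93, 15.93


def deg_points(rng, n, span_m=200.0):
    """Random (lat, lon) points in a span_m x span_m patch."""
    from agrifuse.geodata import meters_per_degree

    m_lat, m_lon = meters_per_degree(LAT0)
    lats = LAT0 + rng.uniform(0, span_m, n) / m_lat
    lons = LON0 + rng.uniform(0, span_m, n) / m_lon
    return lats, lons


def make_samples(lats, lons, values):
    return [
        CovariateSample(lat=la, lon=lo, covariates={}, moisture_estimate=v)
        for la, lo, v in zip(lats, lons, values)
    ]


class TestOrdinaryKriging:
    def test_single_sample_returns_its_value_everywhere(self):
        vgm = VariogramModel("spherical", 0.01, 0.1, 50.0)
        samples = make_samples([LAT0], [LON0], [0.31])
        preds = krige(samples, vgm, [(LAT0 + 1e-4, LON0), (LAT0, LON0 + 5e-4)])
        for est, _ in preds:
            assert est == pytest.approx(0.31, abs=1e-12)

    def test_exact_interpolation_at_sample(self):
        rng = np.random.default_rng(0)
        lats, lons = deg_points(rng, 6)
        vals = rng.uniform(0.1, 0.5, 6)
        vgm = VariogramModel("exponential", 0.0, 1.0, 60.0)
        (est, var), = krige(make_samples(lats, lons, vals), vgm, [(lats[2], lons[2])])
        assert est == pytest.approx(vals[2], abs=1e-10)
        assert var == pytest.approx(0.0, abs=1e-10)

    def test_duplicate_locations_rejected(self):
        vgm = VariogramModel("exponential", 0.0, 1.0, 60.0)
        with pytest.raises(GeometryError):
            krige(make_samples([LAT0, LAT0], [LON0, LON0], [0.2, 0.3]), vgm,
                  [(LAT0 + 1e-4, LON0)])

    @pytest.mark.parametrize("family", ["exponential", "spherical", "gaussian"])
    def test_weights_match_dense_linear_system_oracle(self, family):
        """Implementation weights equal an independently assembled dense solve."""
        rng = np.random.default_rng(17)
        for trial in range(10):
            n = int(rng.integers(5, 21))
            lats, lons = deg_points(rng, n)
            vals = rng.uniform(0.1, 0.5, n)
            vgm = VariogramModel(family, float(rng.uniform(0, 0.02)),
                                 float(rng.uniform(0.05, 1.0)),
                                 float(rng.uniform(20, 150)))
            ok = OrdinaryKriging(np.array(lats), np.array(lons), vals, vgm)
            t_lat, t_lon = deg_points(rng, 1)
            txy = local_xy(t_lat, t_lon, ok.lat0, ok.lon0)
            w, mu = ok.weights(txy)

            # oracle: assemble the augmented system element by element
            xy = local_xy(np.array(lats), np.array(lons), ok.lat0, ok.lon0)
            a = np.zeros((n + 1, n + 1))
            for p in range(n):
                for q in range(n):
                    h = float(np.hypot(*(xy[p] - xy[q])))
                    a[p, q] = float(vgm(np.array(h)))
                a[p, n] = 1.0
                a[n, p] = 1.0
            b = np.zeros(n + 1)
            for p in range(n):
                h = float(np.hypot(*(xy[p] - txy[0])))
                b[p] = float(vgm(np.array(h)))
            b[n] = 1.0
            sol = np.linalg.solve(a, b)
            np.testing.assert_allclose(w[0], sol[:n], atol=1e-8)
            np.testing.assert_allclose(mu[0], sol[n], atol=1e-8)
            assert w[0].sum() == pytest.approx(1.0, abs=1e-10)

    def test_weights_sum_to_one_random_configs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(2, 30))
            lats, lons = deg_points(rng, n)
            vgm = VariogramModel("exponential", 0.01, 0.5, float(rng.uniform(10, 100)))
            ok = OrdinaryKriging(np.array(lats), np.array(lons), rng.uniform(0, 1, n), vgm)
            t = local_xy(*deg_points(rng, 5), ok.lat0, ok.lon0)
            w, _ = ok.weights(t)
            np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-10)

    def test_continuity_approaching_a_sample(self):
        """With nugget=0 the estimate converges to the sample value."""
        rng = np.random.default_rng(5)
        lats, lons = deg_points(rng, 8)
        vals = rng.uniform(0.1, 0.5, 8)
        vgm = VariogramModel("exponential", 0.0, 1.0, 60.0)
        samples = make_samples(lats, lons, vals)
        errs = []
        for off in (1e-5, 1e-6, 1e-7):
            (est, _), = krige(samples, vgm, [(lats[0] + off, lons[0])])
            errs.append(abs(est - vals[0]))
        assert errs[2] < errs[0]
        assert errs[2] < 1e-3


class TestVariogram:
    def test_semivariance_monotone_and_nugget_limit(self):
        for family in ("exponential", "spherical", "gaussian"):
            vgm = VariogramModel(family, 0.1, 1.0, 30.0)
            h = np.linspace(0.01, 120, 200)
            g = vgm(h)
            assert np.all(np.diff(g) >= -1e-12)
            assert vgm(np.array(0.0)) == 0.0
            assert g[0] >= 0.1  # g(0+) >= nugget

    def test_empirical_variogram_matches_pair_loop_oracle(self):
        rng = np.random.default_rng(12)
        xy = rng.uniform(0, 100, (30, 2))
        z = rng.standard_normal(30)
        h, gamma, counts = empirical_variogram(xy, z, n_bins=8)
        # brute-force double loop over all pairs
        pairs = []
        for p in range(30):
            for q in range(p + 1, 30):
                d = float(np.hypot(*(xy[p] - xy[q])))
                pairs.append((d, 0.5 * (z[p] - z[q]) ** 2))
        h_max = max(d for d, _ in pairs) / 2
        edges = np.linspace(0, h_max, 9)
        for centre, g, c in zip(h, gamma, counts):
            b = np.searchsorted(edges, centre) - 1
            members = [sv for d, sv in pairs if edges[b] <= d < edges[b + 1]
                       or (b == 0 and d == 0.0)]
            assert c == len(members)
            assert g == pytest.approx(np.mean(members))

    def test_parameter_recovery_on_simulated_fields(self):
        """Median fit across 5 nested-survey fields recovers range and sill."""
        from agrifuse.geodata import meters_per_degree
        from agrifuse.kriging import nested_survey_xy, sample_gaussian_process

        m_lat, m_lon = meters_per_degree(LAT0)
        true = VariogramModel("exponential", 0.1, 1.0, 30.0)
        fits = []
        for seed in range(5):
            xy = nested_survey_xy(200, 200.0, seed=seed)
            z = sample_gaussian_process(xy, true, seed=seed)
            scale = 0.05 / z.std()
            lats = LAT0 + xy[:, 1] / m_lat
            lons = LON0 + xy[:, 0] / m_lon
            samples = make_samples(lats, lons, np.clip(0.25 + z * scale, 0, 0.57))
            vgm = fit_variogram(samples, family="exponential")
            fits.append((vgm.range_m, vgm.sill / scale**2))
        med_range, med_sill = np.median(np.array(fits), axis=0)
        assert med_range == pytest.approx(30.0, rel=0.30)
        assert med_sill == pytest.approx(1.0, rel=0.25)

    def test_pure_nugget_field(self):
        rng = np.random.default_rng(7)
        lats, lons = deg_points(rng, 150)
        z = np.clip(0.3 + 0.04 * rng.standard_normal(150), 0, 0.57)
        vgm = fit_variogram(make_samples(lats, lons, z), family="exponential")
        # spatially uncorrelated data: structure appears at negligible range
        # or as nugget-dominated variance
        total = vgm.nugget + vgm.sill
        assert total == pytest.approx(np.var(z), rel=0.5)

    def test_identical_values_zero_sill(self):
        rng = np.random.default_rng(8)
        lats, lons = deg_points(rng, 20)
        vgm = fit_variogram(make_samples(lats, lons, np.full(20, 0.3)))
        assert vgm.nugget + vgm.sill == pytest.approx(0.0, abs=1e-9)

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(9)
        lats, lons = deg_points(rng, 5)
        with pytest.raises(InsufficientDataError):
            fit_variogram(make_samples(lats, lons, rng.uniform(0.1, 0.4, 5)))


class TestCovariateModel:
    def test_constant_intercept(self):
        pts = [(LAT0, LON0), (LAT0 + 1e-4, LON0)]
        covs = [{"ndvi": 0.5}, {"ndvi": 0.8}]
        out = estimate_moisture_at_points(pts, covs, {}, intercept=0.3)
        assert [s.moisture_estimate for s in out] == [0.3, 0.3]

    def test_clamped_to_probe_range(self):
        out = estimate_moisture_at_points([(LAT0, LON0)], [{"x": 1.0}], {"x": 2.0})
        assert out[0].moisture_estimate == 0.57

    def test_missing_covariate_rejected(self):
        with pytest.raises(MissingCovariateError):
            estimate_moisture_at_points([(LAT0, LON0)], [{"x": 1.0}], {"y": 1.0})

    def test_linear_link_recovery(self):
        rng = np.random.default_rng(11)
        lats, lons = deg_points(rng, 30)
        truth = rng.uniform(0.15, 0.45, 30)
        covs = [{"raw": t} for t in truth]
        out = estimate_moisture_at_points(list(zip(lats, lons)), covs, {"raw": 1.0})
        np.testing.assert_allclose([s.moisture_estimate for s in out], truth, atol=1e-12)


class TestCalibration:
    def _setup(self, rng, coeff_true=1.0):
        """Smooth moisture field sampled at survey points and probe locations."""
        n = 40
        lats, lons = deg_points(rng, n)
        xy = local_xy(np.array(lats), np.array(lons), LAT0, LON0)

        def field(p):
            return 0.3 + 0.08 * np.sin(p[:, 0] / 60.0) * np.cos(p[:, 1] / 45.0)

        covs = [{"raw": v / coeff_true} for v in field(xy)]
        s_lats, s_lons = deg_points(rng, 5)
        s_xy = local_xy(np.array(s_lats), np.array(s_lons), LAT0, LON0)
        sensors = [
            SensorReading(la, lo, "2021-07-28T09:40:00Z", "soil_moisture_vwc", float(v))
            for la, lo, v in zip(s_lats, s_lons, field(s_xy))
        ]
        return list(zip(lats, lons)), covs, sensors

    def test_single_configuration_grid(self):
        rng = np.random.default_rng(20)
        pts, covs, sensors = self._setup(rng)
        vgm = VariogramModel("exponential", 0.0, 0.01, 80.0)
        res = calibrate_against_sensors(pts, covs, sensors, [vgm], [{"raw": 1.0}])
        assert res.variogram == vgm
        assert res.coefficients == {"raw": 1.0}
        assert len(res.residuals) == 5

    def test_oracle_configuration_beats_distractors(self):
        rng = np.random.default_rng(21)
        pts, covs, sensors = self._setup(rng, coeff_true=1.0)
        vgms = [VariogramModel("exponential", 0.0, 0.01, r) for r in (40.0, 80.0)]
        grid = [{"raw": c} for c in (0.5, 1.0, 2.0)]
        res = calibrate_against_sensors(pts, covs, sensors, vgms, grid)
        assert res.coefficients == {"raw": 1.0}
        assert res.mae < 0.01

    def test_round_trip_recovers_planted_coefficient(self):
        rng = np.random.default_rng(22)
        pts, covs, sensors = self._setup(rng, coeff_true=0.8)
        vgms = [VariogramModel("exponential", 0.0, 0.01, 80.0)]
        grid = [{"raw": c} for c in (0.5, 0.8, 1.0, 1.3)]
        res = calibrate_against_sensors(pts, covs, sensors, vgms, grid)
        assert res.coefficients == {"raw": 0.8}

    def test_requires_moisture_sensors(self):
        rng = np.random.default_rng(23)
        pts, covs, _ = self._setup(rng)
        temp = [SensorReading(LAT0, LON0, "t", "temperature", 25.0)]
        with pytest.raises(SensorKindError):
            calibrate_against_sensors(
                pts, covs, temp, [VariogramModel("exponential", 0, 0.01, 80)],
                [{"raw": 1.0}],
            )
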