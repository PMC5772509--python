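"""Monte Carlo average splines, curve merging, propagation, episodes."""

import numpy as np
import pandas as pd
import pytest

from c3iso.fractionation_models import AtmosState, get_model, predict_delta_p
from c3iso.icecore_curves import (
    Episode,
    SplineCurve,
    detect_episodes,
    expanded_uncertainty,
    mca_spline,
    merge_anthropogenic,
    model_curve,
)


def _series(ages, values, sigma=0.0, outlier=None):
    return pd.DataFrame(
        {
            "age_kyr_bp": ages,
            "value": values,
            "sigma": sigma,
            "outlier": False if outlier is None else outlier,
        }
    )


class TestMcaSpline:
    def test_constant_series_reproduced_exactly(self):
        ages = np.linspace(0, 10, 25)
        c = mca_spline(_series(ages, np.full(25, 240.0)), n_rep=1, seed=0)
        assert np.allclose(c.mean, 240.0, atol=1e-8)
        assert np.allclose(c.sigma, 0.0)

    def test_linear_series_reproduced(self):
        ages = np.linspace(0, 10, 40)
        c = mca_spline(_series(ages, 3.0 * ages + 1.0), n_rep=1, seed=0)
        assert np.allclose(c.mean, 3.0 * c.grid + 1.0, atol=1e-6)

    def test_zero_penalty_interpolates_samples(self):
        ages = np.linspace(0, 10, 40)
        vals = 0.1 * ages**3 - ages**2 + 2.0
        c = mca_spline(
            _series(ages, vals), n_rep=1, seed=0, lam=0.0, grid=ages
        )
        assert np.allclose(c.mean, vals, atol=1e-8)

    def test_outliers_excluded_before_fit(self):
        ages = np.linspace(0, 10, 30)
        vals = np.full(30, 100.0)
        out = np.zeros(30, dtype=bool)
        out[15] = True
        vals[15] = 500.0
        c = mca_spline(_series(ages, vals, outlier=out), n_rep=1, seed=0)
        assert np.allclose(c.mean, 100.0, atol=1e-6)

    def test_ramp_with_noise_covered_by_envelope(self):
        """Monte Carlo mean tracks a known ramp to within its own 2-sigma
        band at nearly all grid points."""
        rng = np.random.default_rng(7)
        ages = np.sort(rng.uniform(0, 30, 250))
        truth = 200.0 + 80.0 / (1.0 + np.exp(-(ages - 15.0) / 1.0))
        c = mca_spline(
            _series(ages, truth + rng.normal(0, 2.0, ages.size), sigma=2.0),
            n_rep=1000,
            seed=1,
        )
        tgrid = 200.0 + 80.0 / (1.0 + np.exp(-(c.grid - 15.0) / 1.0))
        inside = np.abs(c.mean - tgrid) <= 2.0 * c.sigma
        assert inside.mean() >= 0.95

    def test_sigma_monotone_in_noise_scale(self, flat_noisy_series):
        sigmas = []
        for scale in (0.0, 1.0, 3.0):
            s = flat_noisy_series.assign(sigma=scale)
            c = mca_spline(s, n_rep=200, seed=5)
            sigmas.append(c.sigma.mean())
        assert sigmas[0] == pytest.approx(0.0, abs=1e-12)
        assert sigmas[0] < sigmas[1] < sigmas[2]

    def test_mean_stable_under_reseeding(self, flat_noisy_series):
        n_rep = 400
        c1 = mca_spline(flat_noisy_series, n_rep=n_rep, seed=1)
        c2 = mca_spline(flat_noisy_series, n_rep=n_rep, seed=2)
        # difference of two independent MC means, standardised pointwise
        se = np.sqrt(2.0) * np.maximum(c1.sigma, 1e-12) / np.sqrt(n_rep)
        z = (c1.mean - c2.mean) / se
        assert np.mean(z**2) < 2.0
        assert np.max(np.abs(z)) < 5.5

    def test_errors(self, flat_noisy_series):
        with pytest.raises(ValueError):
            mca_spline(flat_noisy_series.head(3), n_rep=10, seed=0)
        with pytest.raises(ValueError):
            mca_spline(
                flat_noisy_series, n_rep=10, seed=0, grid=np.array([-5.0, 1.0])
            )
        with pytest.raises(ValueError):
            mca_spline(flat_noisy_series, n_rep=0, seed=0)


class TestMergeAnthropogenic:
    @staticmethod
    def _pre_curve():
        ages = np.linspace(0.5, 10.0, 60)
        c = mca_spline(_series(ages, np.full(60, 280.0)), n_rep=1, seed=0)
        return c

    def test_empty_modern_returns_pre(self):
        pre = self._pre_curve()
        assert merge_anthropogenic(pre, pd.DataFrame()) is pre

    def test_dense_noiseless_ramp_matched(self):
        pre = self._pre_curve()
        ages = np.arange(-0.05, 0.85, 0.01)
        vals = 280.0 + 90.0 * np.exp(-ages / 0.2)  # steep modern rise
        merged = merge_anthropogenic(pre, _series(ages, vals))
        sel = merged.grid <= 0.5  # clear of the cross-fade at the junction
        truth = 280.0 + 90.0 * np.exp(-merged.grid[sel] / 0.2)
        assert np.allclose(merged.mean[sel], truth, atol=1e-6)

    def test_junction_continuity(self):
        pre = self._pre_curve()
        ages = np.arange(-0.05, 1.3, 0.02)
        merged = merge_anthropogenic(
            pre, _series(ages, np.full(ages.size, 280.0))
        )
        jumps = np.abs(np.diff(merged.mean))
        assert jumps.max() <= 1e-6  # flat truth: no junction artefact

    def test_gap_raises(self):
        pre = self._pre_curve()
        ages = np.arange(-1.0, -0.4, 0.02)  # ends > one grid step early
        with pytest.raises(ValueError):
            merge_anthropogenic(pre, _series(ages, np.full(ages.size, 300.0)))


class TestModelCurve:
    @staticmethod
    def _curves(psig=0.0, dsig=0.0):
        grid = np.linspace(0.0, 10.0, 101)
        pco2 = SplineCurve(grid, np.linspace(270.0, 190.0, 101), np.full(101, psig))
        d13c = SplineCurve(grid, np.full(101, -6.5), np.full(101, dsig))
        return pco2, d13c

    def test_grid_mismatch_raises(self):
        pco2, d13c = self._curves()
        other = SplineCurve(d13c.grid + 1.0, d13c.mean, d13c.sigma)
        with pytest.raises(ValueError):
            model_curve(get_model("sj2012"), pco2, other, seed=0)

    def test_zero_input_sigma_gives_zero_sigma(self):
        pco2, d13c = self._curves()
        c = model_curve(get_model("sj2012"), pco2, d13c, n_rep=100, seed=0)
        assert np.allclose(c.sigma, 0.0)

    def test_farquhar_sigma_tracks_d13c_sigma_exactly(self):
        pco2, d13c = self._curves(psig=2.0, dsig=0.07)
        c = model_curve(get_model("farquhar1982"), pco2, d13c, n_rep=64, seed=3)
        assert np.allclose(c.sigma, 0.07, rtol=1e-9)

    def test_sj_deglacial_change(self):
        """pCO2 190 -> 270 at fixed source: hyperbolic model predicts a
        ~-2 permil depletion."""
        pco2, d13c = self._curves()
        c = model_curve(get_model("sj2012"), pco2, d13c, n_rep=2, seed=0)
        change = c.mean[0] - c.mean[-1]  # young (270) minus old (190)
        assert change == pytest.approx(-2.0, abs=0.1)

    def test_matches_pointwise_prediction(self):
        pco2, d13c = self._curves()
        c = model_curve(get_model("voelker2016g"), pco2, d13c, n_rep=2, seed=0)
        direct = predict_delta_p(
            get_model("voelker2016g"), AtmosState(pco2.mean, d13c.mean)
        )
        assert np.allclose(c.mean, direct)


def test_expanded_uncertainty():
    assert expanded_uncertainty(0.0) == pytest.approx(1.62)
    assert expanded_uncertainty(1.62) == pytest.approx(2.291, abs=1e-3)
    assert expanded_uncertainty(0.5, modern_spread=0.0) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        expanded_uncertainty(-0.1)


class TestDetectEpisodes:
    @staticmethod
    def _ramp_curve():
        grid = np.arange(0.0, 20.0 + 1e-9, 0.1)
        mean = np.interp(grid, [0.0, 8.5, 11.5, 20.0], [-25.0, -25.0, -23.5, -23.5])
        return SplineCurve(grid, mean, np.zeros_like(grid))

    def test_constant_curve_empty(self):
        grid = np.arange(0.0, 20.0, 0.1)
        c = SplineCurve(grid, np.full(grid.size, -25.0), np.zeros_like(grid))
        assert detect_episodes(c) == []

    def test_single_ramp_recovered(self):
        """A 1.5 permil change over 3 kyr (0.5 permil/kyr) amid flat
        background is found as exactly one episode spanning the ramp."""
        eps = detect_episodes(self._ramp_curve())
        assert len(eps) == 1
        e = eps[0]
        assert e.end == pytest.approx(8.5, abs=0.11)
        assert e.start == pytest.approx(11.5, abs=0.11)
        assert e.amplitude == pytest.approx(1.5, abs=0.1)
        assert e.mean_rate == pytest.approx(0.5, abs=0.05)

    def test_exclusion_of_young_interval(self):
        eps = detect_episodes(self._ramp_curve(), exclude_after=12.0)
        assert eps == []

    def test_disjoint_ordered_and_amp_superset(self):
        grid = np.arange(0.0, 40.0 + 1e-9, 0.1)
        mean = np.interp(
            grid,
            [0, 8.5, 11.5, 20, 22, 30, 40],
            [0.0, 0.0, 1.5, 1.5, 2.3, 2.3, 2.3],
        )
        c = SplineCurve(grid, mean, np.zeros_like(grid))
        strict = detect_episodes(c, amp_min=1.0)
        loose = detect_episodes(c, amp_min=0.5)
        assert len(strict) == 1 and len(loose) == 2
        # oldest first, disjoint
        starts = [e.start for e in loose]
        assert starts == sorted(starts, reverse=True)
        for a, b in zip(loose, loose[1:]):
            assert a.end >= b.start
        # lowering amp_min only adds intervals
        strict_spans = {(e.start, e.end) for e in strict}
        loose_spans = {(e.start, e.end) for e in loose}
        assert strict_spans <= loose_spans

    def test_episode_invariants(self):
        with pytest.raises(ValueError):
            Episode(start=1.0, end=2.0, amplitude=1.0, mean_rate=0.5)
        with pytest.raises(ValueError):
            Episode(start=2.0, end=1.0, amplitude=-1.0, mean_rate=0.5)

    def test_synthetic_deglacial_episode_on_truth_curve(self, scenario):
        """On the noise-free synthetic atmosphere, the hyperbolic model
        predicts one rapid high-amplitude episode straddling the ramp."""
        truth = scenario["icecore_truth"]
        grid = np.arange(0.0, 40.0 + 1e-9, 0.1)
        mean = np.asarray(
            predict_delta_p(
                get_model("sj2012"),
                AtmosState(truth.pco2(grid), truth.d13c(grid)),
            )
        )
        c = SplineCurve(grid, mean, np.zeros_like(grid))
        eps = detect_episodes(c, exclude_after=0.2)
        assert len(eps) == 1
        assert eps[0].end < truth.config.ramp_center_kyr < eps[0].start
        assert eps[0].amplitude > 1.0
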