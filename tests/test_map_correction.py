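"""GCM-ensemble precipitation change as an isotopic correction."""

import numpy as np
import pandas as pd
import pytest

from c3iso.map_correction import (
    SECONDS_PER_YEAR,
    cohort_map_effect,
    d13c_map_change,
    ensemble_effect,
    flux_to_mm_per_year,
    site_ensemble_effects,
)
from c3iso.synthetic_data import ScenarioConfig, gen_gcm_ensemble, gen_sites


@pytest.mark.parametrize(
    "lgm, midh, expected",
    [
        (800.0, 800.0, 0.0),
        (500.0, 1000.0, -1.180),   # Holocene wetting depletes plants
        (1000.0, 2000.0, -1.388),  # doubling MAP ~ 1 permil, negative
    ],
)
def test_d13c_map_change_values(lgm, midh, expected):
    assert d13c_map_change(lgm, midh) == pytest.approx(expected, abs=2e-3)


def test_d13c_map_change_antisymmetric():
    rng = np.random.default_rng(0)
    a = rng.uniform(100, 3000, 50)
    b = rng.uniform(100, 3000, 50)
    assert np.allclose(d13c_map_change(a, b), -d13c_map_change(b, a))
    with pytest.raises(ValueError):
        d13c_map_change(-1.0, 500.0)


def test_flux_conversion():
    assert flux_to_mm_per_year(1.0) == SECONDS_PER_YEAR
    # ~1000 mm/yr is a flux of ~3.17e-5 kg m-2 s-1
    assert flux_to_mm_per_year(1000.0 / SECONDS_PER_YEAR) == pytest.approx(1000.0)


def _pairs(effects_lgm, effects_midh, site="S1"):
    return pd.DataFrame(
        {
            "model": [f"m{i}" for i in range(len(effects_lgm))],
            "site_id": site,
            "map_lgm_mm": effects_lgm,
            "map_midh_mm": effects_midh,
        }
    )


class TestEnsembleEffect:
    def test_identical_models_zero_sigma(self):
        p = _pairs([500.0] * 7, [900.0] * 7)
        eff = ensemble_effect(p)
        assert eff.sigma == pytest.approx(0.0, abs=1e-12)
        assert eff.n_models == 7
        assert eff.mean == pytest.approx(d13c_map_change(500.0, 900.0))
        assert eff.fraction_wetter == 1.0

    def test_single_model_raises(self):
        with pytest.raises(ValueError):
            ensemble_effect(_pairs([500.0], [900.0]))

    def test_sigma_tracks_injected_spread(self):
        """Pseudo-GCM ensembles with larger inter-model spread yield a
        larger per-site effect sigma, roughly at the delta-method scale."""
        sigmas = []
        for spread in (0.0, 0.15, 0.3):
            cfg = ScenarioConfig(
                seed=5, n_sites=6, n_gcm=40, gcm_spread=spread,
                gcm_site_spread=0.0,
            )
            sites = gen_sites(cfg)
            tab = gen_gcm_ensemble(cfg, sites)
            per_site = site_ensemble_effects(tab)
            sigmas.append(per_site["sigma"].mean())
        assert sigmas[0] == pytest.approx(0.0, abs=1e-12)
        assert sigmas[0] < sigmas[1] < sigmas[2]
        # delta method: d(effect)/d(log MAP) ~ 2.43 * M/(M+300) per epoch,
        # two independent epochs -> sigma ~ sqrt(2) * 2.43 * f * spread
        assert 0.4 * np.sqrt(2) * 2.43 * 0.3 < sigmas[2] < np.sqrt(2) * 2.43 * 0.3


class TestCohortEffect:
    @staticmethod
    def _records(site_counts):
        rows = []
        for sid, n in site_counts.items():
            rows += [{"site_id": sid, "age_kyr_bp": 25.0}] * n
        return pd.DataFrame(rows)

    def test_all_sites_zero_change(self):
        rec = self._records({"S1": 3, "S2": 2})
        tab = pd.concat(
            [
                _pairs([700.0] * 3, [700.0] * 3, site="S1"),
                _pairs([400.0] * 3, [400.0] * 3, site="S2"),
            ]
        )
        eff = cohort_map_effect(rec, tab)
        assert eff.mean == 0.0 and eff.sigma == 0.0
        assert eff.fraction_wetter == 0.0

    def test_homogeneous_cohort_equals_site_effect(self):
        rec = self._records({"S1": 4, "S2": 6})
        tab = pd.concat(
            [
                _pairs([600.0] * 5, [900.0] * 5, site="S1"),
                _pairs([600.0] * 5, [900.0] * 5, site="S2"),
            ]
        )
        eff = cohort_map_effect(rec, tab)
        assert eff.mean == pytest.approx(d13c_map_change(600.0, 900.0))
        assert eff.sigma == pytest.approx(0.0, abs=1e-12)

    def test_record_weighting(self):
        rec = self._records({"S1": 9, "S2": 1})
        tab = pd.concat(
            [
                _pairs([600.0] * 2, [600.0] * 2, site="S1"),  # zero effect
                _pairs([500.0] * 2, [1000.0] * 2, site="S2"),
            ]
        )
        e_rec = cohort_map_effect(rec, tab)
        e_site = cohort_map_effect(rec, tab, weighting="sites")
        site2 = d13c_map_change(500.0, 1000.0)
        assert e_rec.mean == pytest.approx(0.9 * 0.0 + 0.1 * site2)
        assert e_site.mean == pytest.approx(0.5 * site2)

    def test_invariant_under_row_duplication(self):
        rec = self._records({"S1": 3, "S2": 5})
        tab = pd.concat(
            [
                _pairs([600.0] * 3, [900.0] * 3, site="S1"),
                _pairs([500.0] * 3, [700.0] * 3, site="S2"),
            ]
        )
        base = cohort_map_effect(rec, tab)
        dup = cohort_map_effect(rec, pd.concat([tab, tab.iloc[:3]]))
        assert dup.mean == pytest.approx(base.mean)
        assert dup.sigma == pytest.approx(base.sigma)

    def test_missing_site_raises(self):
        rec = self._records({"S1": 2, "SX": 1})
        tab = _pairs([600.0] * 3, [900.0] * 3, site="S1")
        with pytest.raises(ValueError):
            cohort_map_effect(rec, tab)


def test_synthetic_wetting_sign(scenario):
    """With a drier LGM everywhere in truth, the cohort MAP effect is
    negative and almost all sites are predicted wetter in the Holocene."""
    rec = scenario["records"]
    eff = cohort_map_effect(
        rec[rec["age_kyr_bp"] >= 20.0], scenario["gcm"]
    )
    assert eff.mean < 0
    assert eff.fraction_wetter > 0.85
    assert eff.n_models == 7
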