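"""Record curation, tissue conversions and window statistics."""

import numpy as np
import pandas as pd
import pytest

from c3iso.proxy_records import (
    DEFAULT_WINDOWS,
    OffsetConstants,
    cellulose_to_leaf,
    collagen_to_plant,
    filter_records,
    group_means,
    to_plant_equivalent,
)


def test_tissue_conversions():
    # Holocene faunal adjusted mean, shifted to its plant diet
    assert collagen_to_plant(-21.78) == pytest.approx(-26.88)
    assert collagen_to_plant(-20.0, eps=0.0) == -20.0
    assert cellulose_to_leaf(-25.0) == pytest.approx(-26.0)
    assert cellulose_to_leaf(-25.0, offset=0.0) == -25.0
    # roundtrip
    assert collagen_to_plant(-21.78) + 5.1 == pytest.approx(-21.78)
    with pytest.raises(ValueError):
        OffsetConstants(eps_diet_collagen=-1.0)


def _toy_records():
    return pd.DataFrame(
        {
            "id": list("abcde"),
            "archive": ["collagen"] * 3 + ["cellulose"] * 2,
            "age_kyr_bp": [25.0, 5.0, 0.1, 22.0, 3.0],
            "d13c": [-20.5, -21.5, -22.0, -25.0, -26.0],
            "c3_fraction": [0.99, 0.8, 0.99, 0.995, 0.99],
            "lichen_feeder": [False, False, False, False, True],
        }
    )


def test_to_plant_equivalent_by_archive():
    out = to_plant_equivalent(_toy_records())
    assert out["d13c_plant"].tolist() == pytest.approx(
        [-25.6, -26.6, -27.1, -26.0, -27.0]
    )
    bad = _toy_records().assign(archive="enamel")
    with pytest.raises(ValueError):
        to_plant_equivalent(bad)


class TestFilters:
    def test_toy_counts(self):
        # one low-C3 record and one lichen feeder -> 3 of 5 survive
        out = filter_records(_toy_records(), exclude_industrial=False)
        assert sorted(out["id"]) == ["a", "c", "d"]
        # adding the industrial-era rule also drops the 0.1 kyr record
        assert sorted(filter_records(_toy_records())["id"]) == ["a", "d"]

    def test_no_rules_is_identity(self):
        rec = _toy_records()
        out = filter_records(
            rec,
            min_c3_fraction=None,
            exclude_lichen=False,
            exclude_industrial=False,
        )
        pd.testing.assert_frame_equal(out, rec)

    def test_industrial_exclusion(self):
        rec = _toy_records()
        out = filter_records(
            rec, min_c3_fraction=None, exclude_lichen=False
        )
        assert (out["age_kyr_bp"] >= 0.2).all()
        assert len(out) == len(rec) - 1

    def test_idempotent_and_order_independent(self):
        rec = _toy_records()
        once = filter_records(rec)
        twice = filter_records(once)
        pd.testing.assert_frame_equal(once, twice)
        # c3 filter then lichen filter vs the reverse
        a = filter_records(
            filter_records(rec, exclude_lichen=False, exclude_industrial=False),
            min_c3_fraction=None,
            exclude_industrial=False,
        )
        b = filter_records(
            filter_records(rec, min_c3_fraction=None, exclude_industrial=False),
            exclude_lichen=False,
            exclude_industrial=False,
        )
        pd.testing.assert_frame_equal(a, b)

    def test_empty_result_warns_not_raises(self, caplog):
        rec = _toy_records().assign(c3_fraction=0.1)
        out = filter_records(rec)
        assert out.empty


class TestGroupMeans:
    def test_constant_values(self):
        rec = pd.DataFrame(
            {"age_kyr_bp": [25.0, 24.0, 5.0, 4.0], "d13c": [-21.0] * 4}
        )
        gm = group_means(rec)
        assert gm.loc["pre", "mean"] == -21.0
        assert gm.loc["pre", "sd"] == 0.0
        assert gm.loc["post", "n"] == 2

    def test_empty_window_raises(self):
        rec = pd.DataFrame({"age_kyr_bp": [25.0, 24.0], "d13c": [-21.0, -22.0]})
        with pytest.raises(ValueError):
            group_means(rec)

    def test_windows_are_half_open_and_exclude_industrial(self):
        rec = pd.DataFrame(
            {
                "age_kyr_bp": [25.0, 10.0, 9.9, 0.19, 0.2],
                "d13c": [-20.0, -99.0, -21.0, -99.0, -22.0],
            }
        )
        gm = group_means(rec)
        # 10.0 falls outside 'post' (half-open), 0.19 is industrial
        assert gm.loc["post", "n"] == 2
        assert gm.loc["post", "mean"] == pytest.approx(-21.5)

    def test_injected_shift_recovered(self):
        """A two-cohort series with a known mean difference d returns
        that difference within twice its standard error at the nominal
        ~95% rate over 20 seeds."""
        d, n, hits = -0.93, 250, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rec = pd.DataFrame(
                {
                    "age_kyr_bp": np.r_[
                        rng.uniform(21, 30, n), rng.uniform(1, 9, n)
                    ],
                    "d13c": np.r_[
                        rng.normal(-20.85, 1.0, n),
                        rng.normal(-20.85 + d, 1.0, n),
                    ],
                }
            )
            gm = group_means(rec)
            diff = gm.loc["post", "mean"] - gm.loc["pre", "mean"]
            se = np.hypot(gm.loc["post", "se"], gm.loc["pre", "se"])
            hits += abs(diff - d) <= 2 * se
        assert hits >= 17


def test_archive_offset_consistency(scenario):
    """Collagen and cellulose cohorts generated from the same diet differ
    by ~(5.1 - 1.0) permil, so their plant equivalents coincide."""
    rec = filter_records(scenario["records"])
    hol = rec[(rec["age_kyr_bp"] > 0.2) & (rec["age_kyr_bp"] < 10.0)]
    col = hol[hol["archive"] == "collagen"]["d13c"].mean()
    cel = hol[hol["archive"] == "cellulose"]["d13c"].mean()
    assert col - cel == pytest.approx(5.1 - 1.0, abs=0.25)
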