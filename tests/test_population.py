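"""Population aggregation, bimodality detection, hysteresis, t-tests."""

import numpy as np
import pandas as pd
import pytest

from redoxscope.population import (
    aggregate_timeseries,
    ashman_d,
    assess_hysteresis,
    compare_groups,
    detect_bimodality,
    ratio_histogram,
)


def _meas(ratios_by_frame, interval=20.0, compartment="carboxysome"):
    rows = []
    for f, ratios in ratios_by_frame.items():
        for i, r in enumerate(ratios):
            rows.append(
                dict(object_id=i, frame=f, time_min=f * interval,
                     compartment=compartment, ratio=r)
            )
    return pd.DataFrame(rows)


def test_mean_and_sem_match_hand_computation():
    # sd of {0.1, 0.3} = sqrt(0.02) = 0.14142...; sem = sd/sqrt(2) = 0.1
    s = aggregate_timeseries(_meas({0: [0.1, 0.3]}))
    assert s.mean_ratio.iloc[0] == pytest.approx(0.2)
    assert s["sem"].iloc[0] == pytest.approx(0.1)
    assert s.n.iloc[0] == 2


def test_single_object_frame_has_undefined_sem():
    s = aggregate_timeseries(_meas({0: [0.25]}))
    assert s.mean_ratio.iloc[0] == 0.25 and np.isnan(s["sem"].iloc[0])


def test_burn_in_flags_first_nine_20min_frames():
    s = aggregate_timeseries(
        _meas({f: [0.1, 0.2] for f in range(12)}), burn_in_hours=3.0
    )
    assert s.burn_in.tolist() == [True] * 9 + [False] * 3


def test_aggregation_invariant_to_object_relabeling():
    a = _meas({0: [0.1, 0.2, 0.3]})
    b = a.copy()
    b["object_id"] = [7, 5, 9]
    pd.testing.assert_frame_equal(aggregate_timeseries(a), aggregate_timeseries(b))


def test_undefined_ratios_excluded_from_aggregates():
    df = _meas({0: [0.1, 0.3, np.nan]})
    s = aggregate_timeseries(df)
    assert s.n.iloc[0] == 2 and s.mean_ratio.iloc[0] == pytest.approx(0.2)


# --- histogram -------------------------------------------------------------


def test_identical_ratios_land_in_one_bin():
    h = ratio_histogram([0.15] * 10, bins=30, range=(0.0, 0.3))
    assert h["count"].max() == 10 and (h["count"] > 0).sum() == 1


def test_histogram_frequencies_sum_to_one():
    rng = np.random.default_rng(1)
    h = ratio_histogram(rng.uniform(0, 0.3, 500), bins=20, range=(0.0, 0.3))
    assert h.frequency.sum() == pytest.approx(1.0)


def test_out_of_range_ratio_counted_in_overflow():
    with pytest.warns(UserWarning):
        h = ratio_histogram([0.1, 0.5], bins=3, range=(0.0, 0.3))
    over = h[np.isinf(h.bin_right)]
    assert len(over) == 1 and over["count"].iloc[0] == 1


def test_histogram_rejects_nonpositive_bins():
    with pytest.raises(ValueError):
        ratio_histogram([0.1], bins=0)


# --- bimodality ------------------------------------------------------------


def test_separated_mixture_detected_as_two_components():
    rng = np.random.default_rng(42)
    x = np.concatenate(
        [rng.normal(0.08, 0.02, 250), rng.normal(0.25, 0.02, 250)]
    )
    res = detect_bimodality(x, seed=0)
    assert res.n_components == 2
    assert res.means[0] == pytest.approx(0.08, abs=0.01)
    assert res.means[1] == pytest.approx(0.25, abs=0.01)
    assert sum(res.weights) == pytest.approx(1.0)
    assert res.ashman_d > 2


def test_single_gaussian_detected_as_one_component():
    rng = np.random.default_rng(43)
    res = detect_bimodality(rng.normal(0.15, 0.03, 500), seed=0)
    assert res.n_components == 1


def test_coincident_modes_collapse_to_one_component():
    rng = np.random.default_rng(44)
    x = np.concatenate([rng.normal(0.15, 0.02, 250), rng.normal(0.15, 0.02, 250)])
    assert detect_bimodality(x, seed=0).n_components == 1


def test_insufficient_sample_reported_not_guessed():
    res = detect_bimodality([0.1] * 10, min_n=50)
    assert not res.sufficient and res.n_components == 0


def test_detection_deterministic_given_seed():
    rng = np.random.default_rng(45)
    x = np.concatenate([rng.normal(0.1, 0.02, 300), rng.normal(0.3, 0.02, 300)])
    a, b = detect_bimodality(x, seed=3), detect_bimodality(x, seed=3)
    assert a == b


def test_ashman_d_formula():
    assert ashman_d(0.0, 2.0, 1.0, 1.0) == pytest.approx(2.0)


def test_detection_power_grows_with_separation():
    rng = np.random.default_rng(46)
    base = rng.normal(0.0, 1.0, 400)
    found = []
    for sep in (0.5, 6.0):
        x = np.concatenate([base, rng.normal(sep, 1.0, 400)])
        found.append(detect_bimodality(x, seed=0).n_components)
    assert found == [1, 2]


# --- hysteresis ------------------------------------------------------------


def _series(means, interval=20.0):
    return pd.DataFrame(
        {
            "frame": np.arange(len(means)),
            "time_min": np.arange(len(means)) * interval,
            "mean_ratio": means,
            "sem": 0.01,
            "n": 50,
        }
    )


def test_series_returning_to_baseline_shows_no_hysteresis():
    rng = np.random.default_rng(5)
    means = np.concatenate(
        [np.full(10, 0.30), np.full(10, 0.15), np.full(10, 0.30)]
    ) + rng.normal(0, 0.004, 30)
    res = assess_hysteresis(_series(means), shift_frame=10, window_frames=6,
                            return_frame=20)
    assert abs(res.difference) < 0.01
    assert res.p_value > 0.05


def test_persistent_offset_recovered():
    """A +0.05 persistent post-return offset appears as difference ~ -0.05
    (sign convention: positive = more oxidized before the shift)."""
    rng = np.random.default_rng(6)
    means = np.concatenate(
        [np.full(10, 0.30), np.full(10, 0.15), np.full(10, 0.35)]
    ) + rng.normal(0, 0.004, 30)
    res = assess_hysteresis(_series(means), shift_frame=10, window_frames=6,
                            return_frame=20)
    assert res.difference == pytest.approx(-0.05, abs=0.01)
    assert res.p_value < 0.05


def test_window_longer_than_series_raises():
    with pytest.raises(ValueError):
        assess_hysteresis(_series(np.full(10, 0.3)), shift_frame=5, window_frames=8)


def test_overlapping_windows_rejected():
    # 12 frames, shift at 8, window 5: pre [3,8) overlaps post [7,12)
    with pytest.raises(ValueError):
        assess_hysteresis(_series(np.full(12, 0.3)), shift_frame=8, window_frames=5)


# --- group comparison ------------------------------------------------------


def test_identical_constant_groups_give_p_one():
    with pytest.warns(UserWarning):
        res = compare_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
    assert res.p_value == 1.0 and res.stars == ""


def test_extreme_separation_is_significant():
    a = [0.0, 0.001, -0.001, 0.0005]
    b = [1.0, 1.001, 0.999, 1.0005]
    res = compare_groups(a, b)
    assert res.p_value < 0.05 and res.stars != ""


def test_t_statistic_matches_hand_computed_value():
    # A=[1,2,3], B=[2,4,6]: pooled sp^2=2.5, t = -2/sqrt(2.5*2/3) = -1.549193...
    res = compare_groups([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
    assert res.t_statistic == pytest.approx(-1.5491933384829668, rel=1e-12)


def test_star_thresholds_follow_methods_convention():
    from redoxscope.population import stars_for_p

    assert stars_for_p(0.04) == "*"
    assert stars_for_p(0.0005) == "**"
    assert stars_for_p(0.00005) == "***"
    assert stars_for_p(0.2) == ""


def test_groups_below_two_rejected():
    with pytest.raises(ValueError):
        compare_groups([1.0], [1.0, 2.0])
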