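"""Alpha-sweep morphology, critical points, cross-focality."""

import numpy as np

from tesopt import cross_focality_curves
from tesopt.sweep import BUDGET_SATURATION, patterns_match

I_MAX = 1e-3


def _common_morphology(sweep):
    tbl = sweep.table
    assert sweep.critical_a is not None and sweep.critical_b is not None
    assert sweep.critical_a <= sweep.critical_b
    assert not sweep.failures
    zones = tbl["zone"].to_numpy()
    assert set(zones) == {"pink", "white", "blue"}
    # zones ordered pink -> white -> blue along alpha
    order = {"pink": 0, "white": 1, "blue": 2}
    codes = np.array([order[z] for z in zones])
    assert np.all(np.diff(codes) >= 0)
    # budget below 100% in the pink zone, saturated beyond a
    pct = tbl["budget_pct"].to_numpy()
    assert np.all(pct[zones == "pink"] < 100.0 * BUDGET_SATURATION)
    beyond_a = tbl["alpha"].to_numpy() >= sweep.critical_a
    assert np.all(np.abs(pct[beyond_a] - 100.0) <= 0.5)
    # intensity monotone non-decreasing in alpha
    intensity = tbl["mean_roi_intensity"].to_numpy()
    assert np.all(np.diff(intensity) >= -1e-9 * intensity.max())
    # patterns frozen for alpha >= b
    frozen = [
        p
        for alpha, p in zip(tbl["alpha"], sweep.patterns)
        if alpha >= sweep.critical_b
    ]
    assert len(frozen) >= 2
    for p in frozen:
        assert patterns_match(p, sweep.reciprocity_pattern)
        assert patterns_match(p, frozen[0])


def test_integral_sweep_morphology(sweep_int32):
    _common_morphology(sweep_int32)


def test_elementwise_sweep_morphology(sweep_elem32):
    _common_morphology(sweep_elem32)
    assert sweep_elem32.critical_c is not None


def test_integral_focality_nonincreasing_beyond_a(sweep_int32):
    tbl = sweep_int32.table
    sel = tbl["alpha"].to_numpy() >= sweep_int32.critical_a
    foc = tbl["focality_integral"].to_numpy()[sel]
    assert np.all(np.diff(foc) <= 1e-6 * foc.max())


def test_budget_in_blue_zone_full(sweep_int32):
    tbl = sweep_int32.table
    blue = tbl[tbl["zone"] == "blue"]
    assert np.allclose(blue["used_budget_A"], 2 * I_MAX, rtol=0.005)


def test_cross_focality_table(sweep_int32, sweep_elem32):
    out = cross_focality_curves(sweep_int32, sweep_elem32)
    assert set(out["family"]) == {"integral", "elementwise"}
    n_expected = len(sweep_int32.table) + len(sweep_elem32.table)
    assert len(out) == n_expected
    for col in (
        "alpha",
        "mean_roi_intensity",
        "budget_pct",
        "focality_integral",
        "focality_elementwise",
        "zone",
    ):
        assert col in out.columns


def _assert_dominates(natural, cross, col):
    """At matched mean ROI intensity, the family optimized under a metric is
    at least as focal under it as the other family.  Evaluated at the natural
    family's own (exactly solved) sample points; only the cross curve is
    interpolated, so sparse-grid chords cannot under-report the natural side.
    """
    nat = natural.sort_values("mean_roi_intensity")
    crs = cross.sort_values("mean_roi_intensity")
    lo = max(nat["mean_roi_intensity"].min(), crs["mean_roi_intensity"].min())
    hi = min(nat["mean_roi_intensity"].max(), crs["mean_roi_intensity"].max())
    sel = (nat["mean_roi_intensity"] >= lo) & (nat["mean_roi_intensity"] <= hi)
    pts = nat[sel]
    assert len(pts) >= 3
    crossed = np.interp(
        pts["mean_roi_intensity"], crs["mean_roi_intensity"], crs[col]
    )
    assert np.all(pts[col].to_numpy() >= crossed * (1 - 0.01))


def test_natural_focality_dominates_cross(sweep_int32, sweep_elem32):
    _assert_dominates(sweep_int32.table, sweep_elem32.table, "focality_integral")
    _assert_dominates(sweep_elem32.table, sweep_int32.table, "focality_elementwise")


def test_identical_sweeps_identical_columns(sweep_int32):
    out = cross_focality_curves(sweep_int32, sweep_int32)
    a = out[out["family"] == "integral"].drop(columns="family").reset_index(drop=True)
    b = out[out["family"] == "elementwise"].drop(columns="family").reset_index(drop=True)
    assert a.equals(b)
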