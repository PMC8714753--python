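import numpy as np
import pandas as pd
import pytest
import scipy.stats

from conftest import brute_force_mannwhitney
from herniamech.cohort_stats import (
    compare_groups,
    describe,
    histogram,
    load_registry,
    mann_whitney_u,
    trend_line,
    records_to_frame,
    save_registry,
)
from herniamech.synthetic_data import CohortConfig, GroupSpec, generate_cohort


# -- registry I/O ------------------------------------------------------------

def small_cohort(seed=3, n1=5, n2=4):
    cfg = CohortConfig(
        primary=CohortConfig().primary.__class__(
            **{**CohortConfig().primary.__dict__, "n": n1}),
        recurrent=CohortConfig().recurrent.__class__(
            **{**CohortConfig().recurrent.__dict__, "n": n2}),
        seed=seed,
    )
    return generate_cohort(cfg)[0]


def test_registry_roundtrip_no_rejects(tmp_path):
    records = small_cohort()
    path = tmp_path / "registry.csv"
    save_registry(records, path)
    loaded = load_registry(path)
    assert len(loaded.records) == len(records)
    assert len(loaded.rejects) == 0
    pd.testing.assert_frame_equal(
        records_to_frame(loaded.records), records_to_frame(records), check_dtype=False
    )


def test_invalid_nas_row_rejected_with_reason(tmp_path):
    records = small_cohort()
    df = records_to_frame(records)
    df.loc[0, "nas_rest"] = 11
    path = tmp_path / "registry.csv"
    df.to_csv(path, index=False)
    loaded = load_registry(path)
    assert len(loaded.records) == len(records) - 1
    assert len(loaded.rejects) == 1
    assert "nas_rest" in loaded.rejects.iloc[0]["reject_reason"]


def test_inconsistent_bmi_rejected(tmp_path):
    df = records_to_frame(small_cohort())
    df.loc[0, "bmi"] = 99.0
    path = tmp_path / "r.csv"
    df.to_csv(path, index=False)
    assert "bmi" in load_registry(path).rejects.iloc[0]["reject_reason"]


def test_missing_group_column_is_load_error(tmp_path):
    df = records_to_frame(small_cohort()).drop(columns=["group"])
    path = tmp_path / "registry.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="group"):
        load_registry(path)


# -- descriptives ------------------------------------------------------------

def _counts_frame(total, n, column):
    """n patients whose column values sum to `total` (deterministic split)."""
    base, extra = divmod(total, n)
    vals = [base + 1] * extra + [base] * (n - extra)
    return pd.DataFrame({"group": ["primary"] * n, column: vals})


def test_mean_prior_surgeries_matches_registry_arithmetic():
    s = describe(_counts_frame(227, 119, "prior_surgeries"), "prior_surgeries")
    assert round(s.mean, 1) == 1.9
    assert s.n == 119 and s.missing == 0


def test_mean_risk_factors_matches_registry_arithmetic():
    s = describe(_counts_frame(66, 44, "risk_factor_count"), "risk_factor_count")
    assert round(s.mean, 1) == 1.5


def test_describe_single_value():
    s = describe(pd.DataFrame({"x": [7.0]}), "x")
    assert s.median == s.mean == 7.0 and s.sd == 0.0 and s.range == (7.0, 7.0)


def test_describe_excludes_missing():
    s = describe(pd.DataFrame({"x": [1.0, np.nan, 3.0]}), "x")
    assert s.n == 2 and s.missing == 1 and s.mean == 2.0


# -- Mann-Whitney U ----------------------------------------------------------

def test_separated_samples_exact_p():
    u, p, method = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert u == 0.0 and method == "exact"
    assert p == pytest.approx(0.1)


def test_identical_multisets_u_half_and_p_one():
    x = [3, 1, 4, 1, 5]
    u, p, _ = mann_whitney_u(x, x)
    assert u == len(x) ** 2 / 2
    assert p == 1.0


def test_constant_data_p_one_both_paths():
    assert mann_whitney_u([5.0] * 4, [5.0] * 6)[1] == 1.0
    assert mann_whitney_u([5.0] * 30, [5.0] * 25)[1] == 1.0  # normal path, zero variance


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1, 2])


def test_u_bounded_by_n1_n2():
    rng = np.random.default_rng(5)
    for _ in range(20):
        x, y = rng.normal(size=6), rng.normal(size=9)
        u, _, _ = mann_whitney_u(x, y)
        assert 0 <= u <= len(x) * len(y)


def test_exact_p_equals_brute_force_enumeration():
    """DP-based exact null distribution equals exhaustive enumeration, ties included."""
    rng = np.random.default_rng(11)
    for n1 in range(2, 7):
        for n2 in range(2, 7):
            x = rng.integers(0, 5, size=n1).astype(float)  # ties across samples
            y = rng.integers(0, 5, size=n2).astype(float)
            u_impl, p_impl, method = mann_whitney_u(x, y)
            u_ref, p_ref = brute_force_mannwhitney(x, y)
            assert method == "exact"
            assert u_impl == pytest.approx(u_ref)
            assert p_impl == pytest.approx(p_ref, abs=1e-12)


def test_tie_free_exact_agrees_with_scipy():
    rng = np.random.default_rng(2)
    for _ in range(10):
        x = rng.normal(size=7)
        y = rng.normal(size=8)
        _, p, _ = mann_whitney_u(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


def test_exact_and_normal_agree_for_tie_free_n8():
    """The continuity-corrected normal approximation tracks the exact null to
    about one percentage point of p already at n1 = n2 = 8."""
    rng = np.random.default_rng(4)
    diffs = []
    for _ in range(10):
        x, y = rng.normal(size=8), rng.normal(size=8)
        _, p_exact, _ = mann_whitney_u(x, y)
        _, p_norm, _ = mann_whitney_u(x, y, exact_max_n=1)
        diffs.append(abs(p_exact - p_norm))
    assert max(diffs) < 0.015
    assert np.median(diffs) < 0.01


def test_u_invariant_under_monotone_transform():
    rng = np.random.default_rng(9)
    x, y = rng.normal(size=10), rng.normal(size=12) + 0.5
    u0, p0, _ = mann_whitney_u(x, y)
    for f in (np.exp, lambda v: v**3, lambda v: 5 * v - 2):
        u, p, _ = mann_whitney_u(f(x), f(y))
        assert u == pytest.approx(u0) and p == pytest.approx(p0)


# -- group comparisons -------------------------------------------------------

def test_shifted_medians_detected_in_most_replicates():
    """A twofold median shift at registry-scale n yields p < 0.05 nearly always."""
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "group": ["primary"] * 30 + ["recurrent"] * 30,
            "hernia_area": np.concatenate([
                rng.lognormal(np.log(78), 0.45, 30),
                rng.lognormal(np.log(161), 0.45, 30),
            ]),
        })
        [c] = compare_groups(df, ["hernia_area"])
        hits += c.p_value < 0.05
    assert hits >= 18


def test_identical_groups_rarely_significant():
    calm = 0
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        df = pd.DataFrame({
            "group": ["primary"] * 30 + ["recurrent"] * 30,
            "x": rng.lognormal(4.0, 0.5, 60),
        })
        [c] = compare_groups(df, ["x"])
        calm += c.p_value > 0.05
    assert calm >= 18


def test_constant_variable_p_one():
    df = pd.DataFrame({"group": ["primary"] * 10 + ["recurrent"] * 10, "x": [3.0] * 20})
    [c] = compare_groups(df, ["x"])
    assert c.p_value == 1.0 and c.method == "exact"


def test_compare_requires_two_per_group():
    df = pd.DataFrame({"group": ["primary", "primary", "recurrent"], "x": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError):
        compare_groups(df, ["x"])


def test_holm_adjustment_monotone():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({
        "group": ["primary"] * 25 + ["recurrent"] * 25,
        "a": np.concatenate([rng.normal(0, 1, 25), rng.normal(2, 1, 25)]),
        "b": rng.normal(size=50),
        "c": rng.normal(size=50),
    })
    comps = compare_groups(df, ["a", "b", "c"], holm=True)
    for c in comps:
        assert c.p_adjusted is not None and c.p_adjusted >= c.p_value


# -- trend line and histogram ------------------------------------------------

def test_trend_line_perfect_correlation():
    df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [3.0, 5, 7, 9]})
    slope, intercept, r = trend_line(df, "x", "y")
    assert slope == pytest.approx(2.0) and intercept == pytest.approx(1.0)
    assert r == pytest.approx(1.0)


def test_trend_line_independent_data_near_zero():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"x": rng.normal(size=500), "y": rng.normal(size=500)})
    _, _, r = trend_line(df, "x", "y")
    assert abs(r) < 0.1


def test_trend_line_two_points_rejected():
    df = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]})
    with pytest.raises(ValueError):
        trend_line(df, "x", "y")


def test_histogram_basic_binning():
    df = pd.DataFrame({"x": [10.0, 20.0, 30.0]})
    h = histogram(df, "x", 15.0)
    assert list(h.counts[:3]) == [1, 1, 1]
    assert h.median == 20.0


def test_histogram_truncation_overflow():
    df = pd.DataFrame({"x": [20.0, 100.0, 1800.0]})
    h = histogram(df, "x", 40.0, truncate_at=360.0)
    assert h.overflow == 1
    assert h.counts.sum() == 2
    assert h.median == 100.0  # median computed before truncation


def test_histogram_empty_selection():
    df = pd.DataFrame({"x": [np.nan, np.nan]})
    h = histogram(df, "x", 10.0)
    assert h.counts.size == 0 and h.overflow == 0 and h.median is None
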