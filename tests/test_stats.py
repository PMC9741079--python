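"""Class binning, amplitude summaries, the variance-ratio F test (checked
against direct numeric integration of the F density), Bonferroni, trends and
the panel-level analyze table."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from tunnelmetrics import (
    DimensionGenSpec,
    MeasurementDataset,
    ValidationError,
    amplitude_fold_ratio,
    analyze,
    assign_class,
    bonferroni_adjust,
    class_summary,
    fit_trend,
    generate_dimension_dataset,
    mean_difference_test,
    variance_ratio_test,
)


def f_tail_by_integration(f: float, d1: int, d2: int) -> float:
    """Independent oracle: P(F >= f) by quadrature of the F density."""

    def pdf(x: float) -> float:
        c = (
            math.gamma((d1 + d2) / 2)
            / (math.gamma(d1 / 2) * math.gamma(d2 / 2))
            * (d1 / d2) ** (d1 / 2)
        )
        return c * x ** (d1 / 2 - 1) * (1 + d1 * x / d2) ** (-(d1 + d2) / 2)

    val, _ = quad(pdf, f, np.inf)
    return val


@pytest.mark.parametrize(
    "t_opt,expected",
    [(37.0, "<50"), (49.999, "<50"), (50.0, "50-80"), (80.0, "50-80"),
     (80.001, ">80"), (110.0, ">80"), (18.0, "<50")],
)
def test_assign_class(t_opt, expected):
    assert assign_class(t_opt) == expected


def test_assign_class_partitions_range():
    ts = np.linspace(0.01, 129.99, 5000)
    classes = {assign_class(t) for t in ts}
    assert classes == {"<50", "50-80", ">80"}
    # monotone: class index never decreases with temperature
    order = {"<50": 0, "50-80": 1, ">80": 2}
    idx = [order[assign_class(t)] for t in ts]
    assert idx == sorted(idx)


def test_assign_class_rejects_nonpositive():
    with pytest.raises(ValidationError):
        assign_class(0.0)


def test_class_summary_hand_example():
    s = class_summary([2, 5, 9])
    assert s.n == 3
    assert s.amplitude == pytest.approx(7.0)
    assert s.mean == pytest.approx(16 / 3)
    assert s.sd == pytest.approx(math.sqrt(((2 - 16 / 3) ** 2 + (5 - 16 / 3) ** 2 + (9 - 16 / 3) ** 2) / 2))
    assert s.sd == pytest.approx(3.511885, abs=1e-6)


def test_class_summary_singleton_and_order_invariance(rng):
    single = class_summary([4.2])
    assert single.amplitude == 0.0 and single.n == 1 and math.isnan(single.sd)
    vals = rng.uniform(0, 10, size=20)
    a, b = class_summary(vals), class_summary(vals[::-1])
    assert (a.mean, a.sd, a.amplitude) == (b.mean, b.sd, b.amplitude)
    with pytest.raises(ValidationError):
        class_summary([])


def test_class_summary_translation_and_scale(rng):
    vals = rng.normal(5, 2, size=15)
    base = class_summary(vals)
    shifted = class_summary(vals + 100)
    assert shifted.amplitude == pytest.approx(base.amplitude)
    assert shifted.sd == pytest.approx(base.sd)
    scaled = class_summary(vals * 3)
    assert scaled.sd == pytest.approx(3 * base.sd)
    assert scaled.amplitude == pytest.approx(3 * base.amplitude)


def test_variance_ratio_identical_samples():
    res = variance_ratio_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.f_stat == pytest.approx(1.0)
    assert res.p_raw == pytest.approx(1.0)


def test_variance_ratio_against_integration_oracle(rng):
    """Samples built to have variances 4 and 1 at n=11: F=4, df (10,10)."""
    base = rng.normal(size=11)
    base = (base - base.mean()) / base.std(ddof=1)  # exact unit sample variance
    a, b = 2.0 * base, base
    res = variance_ratio_test(a, b)
    assert res.f_stat == pytest.approx(4.0, rel=1e-12)
    assert (res.df_a, res.df_b) == (10, 10)
    expected_p = 2 * f_tail_by_integration(4.0, 10, 10)
    assert res.p_raw == pytest.approx(expected_p, rel=1e-6)
    assert expected_p == pytest.approx(0.0392, abs=5e-4)


def test_variance_ratio_symmetry(rng):
    a = rng.normal(0, 3, size=9)
    b = rng.normal(0, 1, size=14)
    r1 = variance_ratio_test(a, b)
    r2 = variance_ratio_test(b, a)
    assert r1.f_stat == r2.f_stat
    assert r1.p_raw == r2.p_raw


def test_variance_ratio_degenerate_inputs():
    flat = [2.0, 2.0, 2.0]
    assert not variance_ratio_test(flat, flat).testable
    res = variance_ratio_test([1.0, 2.0, 3.0], flat)
    assert math.isinf(res.f_stat) and res.p_raw == 0.0
    with pytest.raises(ValidationError):
        variance_ratio_test([1.0], [1.0, 2.0])


def test_variance_ratio_null_uniformity(rng):
    """Under the equal-variance normal null, p-values are Uniform(0,1)."""
    from scipy import stats as sps

    ps = np.array(
        [
            variance_ratio_test(rng.normal(size=10), rng.normal(size=10)).p_raw
            for _ in range(2000)
        ]
    )
    assert sps.kstest(ps, "uniform").pvalue > 0.01
    assert abs((ps < 0.05).mean() - 0.05) < 0.015


def test_bonferroni():
    assert bonferroni_adjust([0.01], 2) == [0.02]
    assert bonferroni_adjust([0.6], 3) == [1.0]
    raw = [0.001, 0.02, 0.3, 0.04]
    adj = bonferroni_adjust(raw, 4)
    assert np.argsort(adj).tolist() == np.argsort(raw).tolist()  # monotone
    with pytest.raises(ValidationError):
        bonferroni_adjust([1.2], 2)
    with pytest.raises(ValidationError):
        bonferroni_adjust([0.1, 0.2], 1)


def test_fit_trend_exact_line():
    t = fit_trend([0, 1, 2, 3], [1, 3, 5, 7])
    assert t.slope == pytest.approx(2.0)
    assert t.intercept == pytest.approx(1.0)
    assert t.r_squared == pytest.approx(1.0)


def test_fit_trend_constant_and_errors():
    t = fit_trend([0, 1, 2], [4, 4, 4])
    assert t.slope == 0.0 and t.r_squared == 0.0
    with pytest.raises(ValidationError):
        fit_trend([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValidationError):
        fit_trend([1, 2], [1, 2])


def test_fit_trend_recovers_true_slope(rng):
    """Estimated slope within 3 SE of truth in >= 99% of replicates."""
    hits = 0
    n_rep = 300
    beta = 0.8
    for _ in range(n_rep):
        x = rng.uniform(18, 110, size=40)
        y = 5.0 + beta * x + rng.normal(0, 10, size=40)
        t = fit_trend(x, y)
        # standard error of the OLS slope
        resid = y - (t.intercept + t.slope * x)
        se = math.sqrt((resid @ resid) / (len(x) - 2) / ((x - x.mean()) @ (x - x.mean())))
        if abs(t.slope - beta) <= 3 * se:
            hits += 1
    assert hits / n_rep >= 0.99 - 0.02


def test_mean_difference_test_matches_location_shift(rng):
    a = rng.normal(0, 1, size=40)
    t, p = mean_difference_test(a, a + 5.0)
    assert p < 1e-6
    t2, p2 = mean_difference_test(a, a)
    assert p2 == pytest.approx(1.0)


def _toy_dataset(rows):
    return MeasurementDataset(
        pd.DataFrame(
            rows,
            columns=["species", "enzyme", "subunit", "t_opt", "length", "surface", "volume"],
        )
    )


def test_amplitude_fold_ratio_direct():
    rows = [
        ("a", "Mmr", "alpha", 30, 0.0, 1, 1),
        ("b", "Mmr", "alpha", 40, 7.0, 2, 2),
        ("c", "Mmr", "alpha", 90, 3.0, 1, 1),
        ("d", "Mmr", "alpha", 100, 4.0, 2, 2),
    ]
    ratios = amplitude_fold_ratio(_toy_dataset(rows), "length")
    assert ratios[("Mmr", "alpha")] == pytest.approx(7.0)
    # identical spreads -> 1.0 on the surface dimension
    assert amplitude_fold_ratio(_toy_dataset(rows), "surface")[("Mmr", "alpha")] == pytest.approx(1.0)


def test_amplitude_fold_ratio_zero_amplitude_flagged():
    rows = [
        ("a", "Mmr", "alpha", 30, 0.0, 1, 1),
        ("b", "Mmr", "alpha", 40, 7.0, 2, 2),
        ("c", "Mmr", "alpha", 90, 3.0, 1, 1),
        ("d", "Mmr", "alpha", 100, 3.0, 2, 2),
    ]
    assert math.isnan(amplitude_fold_ratio(_toy_dataset(rows), "length")[("Mmr", "alpha")])


def test_analyze_panel_bookkeeping():
    """Default synthetic dataset: 18 panels x 2 comparisons, all testable."""
    ds = generate_dimension_dataset(DimensionGenSpec(n_per_class=10, seed=3))
    res = analyze(ds)
    assert len(res) == 18 * 2
    assert res["testable"].all()
    assert set(res["class_cmp"]) == {"50-80", ">80"}
    assert (res["class_ref"] == "<50").all()
    # Bonferroni with m=2 doubles (then caps) every raw p
    expected = np.minimum(1.0, 2 * res["var_p_raw"])
    assert np.allclose(res["var_p_adj"], expected)


def test_analyze_single_class_flags_untestable():
    rows = [("s%d" % i, "Hdr", "A", 30 + i, 10.0 + i, 20.0, 30.0) for i in range(5)]
    res = analyze(_toy_dataset(rows))
    assert not res["testable"].any()
    assert (res["n_cmp"] == 0).all()
    assert (res["n_ref"] == 5).all()


def test_analyze_row_order_invariance():
    ds = generate_dimension_dataset(DimensionGenSpec(n_per_class=8, seed=11))
    shuffled = MeasurementDataset(
        ds.frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
    )
    a = analyze(ds).reset_index(drop=True)
    b = analyze(shuffled).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_analyze_empty_dataset_errors():
    import io

    from tunnelmetrics import read_dataset_table

    ds = read_dataset_table(io.StringIO(""))
    with pytest.raises(ValidationError):
        analyze(ds)
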