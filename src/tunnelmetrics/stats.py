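"""Temperature-class statistics for channel dimensions.

The scientific question: does the *variability* of channel dimensions
(length, lateral surface, volume) contract as the optimum growth
temperature T_opt of the source organism rises?  Species are binned into
three growth-temperature classes — ``<50`` °C (mesophilic-leaning),
``50-80`` °C (thermophilic) and ``>80`` °C (hyperthermophilic) — and per
class each dimension is summarized by its n, mean, sample SD and
*amplitude* (max − min), the variability statistic.  Classes are compared
against the ``<50`` reference with a two-sided variance-ratio F test
(larger variance in the numerator), Bonferroni-adjusted over the two
comparisons of a panel; means are compared with Welch's t test to show
that location, unlike spread, does not shift.  Linear trends of each
dimension against T_opt are fit by ordinary least squares.

A *panel* is one (enzyme, subunit, dimension) combination, mirroring one
subplot of a per-enzyme figure grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

CLASSES = ("<50", "50-80", ">80")
REFERENCE_CLASS = "<50"
DIMENSIONS = ("length", "surface", "volume")


def assign_class(t_opt: float) -> str:
    """Bin an optimum growth temperature (°C) into its class.

    Strictly below 50 → ``<50``; strictly above 80 → ``>80``; the closed
    interval [50, 80], endpoints included, → ``50-80``.
    """
    t = float(t_opt)
    if not math.isfinite(t) or t <= 0:
        raise ValidationError(f"t_opt must be finite and > 0 degC, got {t_opt!r}")
    if t < 50:
        return "<50"
    if t <= 80:
        return "50-80"
    return ">80"


@dataclass(frozen=True)
class ClassSummary:
    """Descriptive summary of one dimension within one temperature class."""

    t_class: str
    n: int
    mean: float
    sd: float  # NaN when n < 2 (sample SD undefined)
    amplitude: float  # max - min

    @property
    def sd_defined(self) -> bool:
        return self.n >= 2


def class_summary(values: Sequence[float], t_class: str = "") -> ClassSummary:
    """n, arithmetic mean, sample SD (n−1 denominator) and amplitude (max − min)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("class_summary requires at least one value")
    sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else float("nan")
    return ClassSummary(
        t_class=t_class,
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=sd,
        amplitude=float(arr.max() - arr.min()),
    )


@dataclass(frozen=True)
class ComparisonResult:
    """A two-sample variance-ratio comparison, optionally Bonferroni-adjusted."""

    class_a: str
    class_b: str
    f_stat: float
    df_a: int
    df_b: int
    p_raw: float
    p_adjusted: float | None = None
    significant: bool | None = None
    testable: bool = True


def variance_ratio_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    class_a: str = "a",
    class_b: str = "b",
) -> ComparisonResult:
    """Two-sided F test of equal variances.

    The larger sample variance goes in the numerator, so F >= 1; the
    two-sided p-value is min(1, 2 * P(F >= f)) with (n−1, n−1) degrees of
    freedom.  Swapping the samples changes nothing.  With zero variance in
    both samples the comparison is flagged untestable.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("variance_ratio_test requires n >= 2 in each sample")
    va = float(np.var(a, ddof=1))
    vb = float(np.var(b, ddof=1))
    if va == 0.0 and vb == 0.0:
        return ComparisonResult(class_a, class_b, float("nan"), a.size - 1,
                                b.size - 1, float("nan"), testable=False)
    # orient so the larger variance is the numerator
    if va >= vb:
        num_v, den_v = va, vb
        df_num, df_den = a.size - 1, b.size - 1
    else:
        num_v, den_v = vb, va
        df_num, df_den = b.size - 1, a.size - 1
    if den_v == 0.0:
        f_stat, p_raw = float("inf"), 0.0
    else:
        f_stat = num_v / den_v
        p_raw = min(1.0, 2.0 * float(sps.f.sf(f_stat, df_num, df_den)))
    return ComparisonResult(class_a, class_b, f_stat, df_num, df_den, p_raw)


def mean_difference_test(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Welch's t test of equal means; returns (t statistic, two-sided p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("mean_difference_test requires n >= 2 in each sample")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def bonferroni_adjust(p_values: Sequence[float], m: int) -> list[float]:
    """Bonferroni adjustment: p_adj = min(1, m * p), order preserved."""
    ps = list(p_values)
    if m < len(ps):
        raise ValidationError(f"family size m={m} smaller than {len(ps)} p-values")
    for p in ps:
        if not math.isnan(p) and not (0.0 <= p <= 1.0):
            raise ValidationError(f"p-value outside [0, 1]: {p}")
    return [p if math.isnan(p) else min(1.0, m * p) for p in ps]


@dataclass(frozen=True)
class TrendLine:
    """OLS fit of a dimension against T_opt."""

    slope: float  # dimension units per °C
    intercept: float
    r_squared: float


def fit_trend(t_opt: Sequence[float], values: Sequence[float]) -> TrendLine:
    """Ordinary least squares of ``values`` on ``t_opt``."""
    x = np.asarray(t_opt, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValidationError("fit_trend requires >= 3 points")
    if np.unique(x).size < 2:
        raise ValidationError("fit_trend requires >= 2 distinct t_opt values")
    if np.var(y) == 0.0:
        # constant response: flat line, no variance explained
        return TrendLine(0.0, float(y.mean()), 0.0)
    res = sps.linregress(x, y)
    return TrendLine(float(res.slope), float(res.intercept), float(res.rvalue) ** 2)


def amplitude_fold_ratio(
    dataset: "MeasurementDataset", dimension: str
) -> dict[tuple[str, str], float]:
    """Per (enzyme, subunit): amplitude(``<50``) / amplitude(``>80``).

    The headline contraction statistic: how many times wider the dimension's
    range is in the coolest class than in the hottest.  NaN flags an
    undefined ratio (zero amplitude in the ``>80`` class).  Requires both
    classes present with n >= 2 for every (enzyme, subunit) in the dataset.
    """
    _require_dimension(dimension)
    out: dict[tuple[str, str], float] = {}
    for (enzyme, subunit), grp in dataset.frame.groupby(["enzyme", "subunit"], sort=True):
        lo = grp.loc[grp["t_class"] == "<50", dimension].to_numpy()
        hi = grp.loc[grp["t_class"] == ">80", dimension].to_numpy()
        if lo.size < 2 or hi.size < 2:
            raise ValidationError(
                f"({enzyme}, {subunit}): amplitude fold ratio needs n >= 2 in "
                f"both the <50 and >80 classes"
            )
        amp_hi = float(hi.max() - hi.min())
        amp_lo = float(lo.max() - lo.min())
        out[(enzyme, subunit)] = amp_lo / amp_hi if amp_hi > 0 else float("nan")
    return out


def _require_dimension(dimension: str) -> None:
    if dimension not in DIMENSIONS:
        raise ValidationError(f"dimension must be one of {DIMENSIONS}, got {dimension!r}")


def analyze(
    dataset: "MeasurementDataset",
    alpha: float = 0.05,
    bonferroni_m: int = 2,
) -> pd.DataFrame:
    """Full per-panel analysis of a measurement dataset.

    For every (enzyme, subunit, dimension) panel: the three class summaries,
    the two comparisons of ``50-80`` and ``>80`` against the ``<50``
    reference (variance-ratio F test and Welch mean test, both
    Bonferroni-adjusted with family size ``bonferroni_m`` within the
    panel), the ``<50``/``>80`` amplitude fold ratio, and the OLS trend of
    the dimension on T_opt.  One output row per panel × comparison; panels
    whose comparison classes are empty or too small are kept with
    ``testable=False`` rather than dropped.  Row order of the input never
    affects the result.
    """
    frame = dataset.frame
    if frame.empty:
        raise ValidationError("cannot analyze an empty dataset")
    rows = []
    for (enzyme, subunit), grp in frame.groupby(["enzyme", "subunit"], sort=True):
        by_class = {c: grp.loc[grp["t_class"] == c] for c in CLASSES}
        for dimension in DIMENSIONS:
            values = {c: by_class[c][dimension].to_numpy() for c in CLASSES}
            summaries = {
                c: class_summary(values[c], c) if values[c].size else None
                for c in CLASSES
            }
            ref = values[REFERENCE_CLASS]
            # fold ratio and trend are panel-level; repeated on both rows
            lo, hi = values["<50"], values[">80"]
            if lo.size >= 2 and hi.size >= 2 and (hi.max() - hi.min()) > 0:
                fold = float((lo.max() - lo.min()) / (hi.max() - hi.min()))
            else:
                fold = float("nan")
            t_all = grp["t_opt"].to_numpy()
            try:
                trend = fit_trend(t_all, grp[dimension].to_numpy())
            except ValidationError:
                trend = TrendLine(float("nan"), float("nan"), float("nan"))

            comparisons = []
            for other in ("50-80", ">80"):
                if ref.size >= 2 and values[other].size >= 2:
                    comp = variance_ratio_test(
                        ref, values[other], REFERENCE_CLASS, other
                    )
                    if comp.testable:
                        mean_t, mean_p = mean_difference_test(ref, values[other])
                    else:
                        mean_t, mean_p = float("nan"), float("nan")
                else:
                    comp = ComparisonResult(
                        REFERENCE_CLASS, other, float("nan"), 0, 0, float("nan"),
                        testable=False,
                    )
                    mean_t, mean_p = float("nan"), float("nan")
                comparisons.append((other, comp, mean_t, mean_p))

            var_adj = bonferroni_adjust([c.p_raw for _, c, _, _ in comparisons],
                                        bonferroni_m)
            mean_adj = bonferroni_adjust([mp for _, _, _, mp in comparisons],
                                         bonferroni_m)
            for (other, comp, mean_t, mean_p), vp, mp in zip(
                comparisons, var_adj, mean_adj
            ):
                s_ref = summaries[REFERENCE_CLASS]
                s_cmp = summaries[other]
                rows.append(
                    {
                        "enzyme": enzyme,
                        "subunit": subunit,
                        "dimension": dimension,
                        "class_ref": REFERENCE_CLASS,
                        "class_cmp": other,
                        "n_ref": s_ref.n if s_ref else 0,
                        "n_cmp": s_cmp.n if s_cmp else 0,
                        "mean_ref": s_ref.mean if s_ref else float("nan"),
                        "mean_cmp": s_cmp.mean if s_cmp else float("nan"),
                        "sd_ref": s_ref.sd if s_ref else float("nan"),
                        "sd_cmp": s_cmp.sd if s_cmp else float("nan"),
                        "amplitude_ref": s_ref.amplitude if s_ref else float("nan"),
                        "amplitude_cmp": s_cmp.amplitude if s_cmp else float("nan"),
                        "f_stat": comp.f_stat,
                        "df_num": comp.df_a,
                        "df_den": comp.df_b,
                        "var_p_raw": comp.p_raw,
                        "var_p_adj": vp,
                        "var_significant": (vp < alpha) if comp.testable else False,
                        "mean_t_stat": mean_t,
                        "mean_p_raw": mean_p,
                        "mean_p_adj": mp,
                        "mean_significant": (
                            (mp < alpha) if not math.isnan(mp) else False
                        ),
                        "testable": comp.testable,
                        "fold_ratio_lt50_gt80": fold,
                        "trend_slope": trend.slope,
                        "trend_intercept": trend.intercept,
                        "trend_r_squared": trend.r_squared,
                    }
                )
    return pd.DataFrame(rows)


# imported late to avoid a cycle at module import time
from .channel_model import MeasurementDataset  # noqa: E402
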