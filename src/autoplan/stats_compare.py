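"""Paired plan-comparison statistics and the mean-dose-vs-overlap regression.

The plan comparison uses the two-sided Wilcoxon signed-rank test, with zero
differences dropped before ranking (Wilcoxon's original treatment).  For up
to 12 nonzero pairs the exact null distribution is enumerated over all sign
assignments; beyond that a normal approximation with tie correction and
continuity correction is used.

The regression recipe relates each OAR's EUD with a = 1 (its mean dose) to
its overlap with the PTV (fraction for bladder/rectum, absolute cc for the
bowel bag) across a cohort of evaluated plans, by ordinary least squares
with the Pearson correlation reported alongside.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .evaluation import PlanMetrics

__all__ = [
    "WilcoxonResult",
    "PairedComparison",
    "RegressionFit",
    "wilcoxon_signed_rank",
    "compare_plans",
    "linfit_pearson",
    "COMPARISON_METRICS",
    "metrics_table",
]

EXACT_ENUMERATION_MAX_N = 12
SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float          # sum of positive ranks (after dropping zeros)
    p_value: float
    n_nonzero: int
    degenerate: bool          # all differences were zero
    exact: bool


def _signed_ranks(diff: np.ndarray) -> np.ndarray:
    """Average ranks of |diff| (zeros already removed)."""
    return sps.rankdata(np.abs(diff))


def wilcoxon_signed_rank(a, b) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Returns p = 1 with a degeneracy flag when every difference is zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    diff = diff[diff != 0]
    n = diff.size
    if n == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_nonzero=0,
                              degenerate=True, exact=True)
    ranks = _signed_ranks(diff)
    w_pos = float(ranks[diff > 0].sum())

    if n <= EXACT_ENUMERATION_MAX_N:
        # exact null: every sign assignment equally likely
        total = 0
        le = 0
        ge = 0
        for signs in itertools.product((0, 1), repeat=n):
            w = float(np.dot(signs, ranks))
            total += 1
            le += w <= w_pos + 1e-12
            ge += w >= w_pos - 1e-12
        p = min(1.0, 2.0 * min(le, ge) / total)
        return WilcoxonResult(w_pos, p, n, degenerate=False, exact=True)

    # normal approximation with tie correction and continuity correction
    mu = n * (n + 1) / 4.0
    tie_term = 0.0
    _, counts = np.unique(np.abs(diff), return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    sigma = np.sqrt(sigma2)
    if sigma == 0:
        return WilcoxonResult(w_pos, 1.0, n, degenerate=True, exact=False)
    z = (w_pos - mu - 0.5 * np.sign(w_pos - mu)) / sigma
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return WilcoxonResult(w_pos, float(p), n, degenerate=False, exact=False)


@dataclass(frozen=True)
class PairedComparison:
    metric: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    p_value: float
    significant: bool
    degenerate: bool

    def formatted(self) -> dict[str, str | float]:
        return {
            "metric": self.metric,
            "arm_a": f"{self.mean_a:.2f} ± {self.sd_a:.2f}",
            "arm_b": f"{self.mean_b:.2f} ± {self.sd_b:.2f}",
            "p": self.p_value,
            "significant": self.significant,
        }


#: (row label, extractor) — the dosimetric comparison row list
COMPARISON_METRICS: list[tuple[str, callable]] = [
    ("PTV D_max (Gy)", lambda m: m.per_roi["PTV"]["D_max"]),
    ("PTV D_98% (Gy)", lambda m: m.per_roi["PTV"]["D_98%"]),
    ("PTV D_2% (Gy)", lambda m: m.per_roi["PTV"]["D_2%"]),
    ("CI", lambda m: m.ci),
    ("HI", lambda m: m.hi),
    ("bladder D_0.03cc (Gy)", lambda m: m.per_roi["bladder"]["D_0.03cc"]),
    ("bladder V_50Gy (%)", lambda m: m.per_roi["bladder"]["V_50Gy"]),
    ("bladder V_40Gy (%)", lambda m: m.per_roi["bladder"]["V_40Gy"]),
    ("bladder D_mean (Gy)", lambda m: m.per_roi["bladder"]["D_mean"]),
    ("rectum D_0.03cc (Gy)", lambda m: m.per_roi["rectum"]["D_0.03cc"]),
    ("rectum V_50Gy (%)", lambda m: m.per_roi["rectum"]["V_50Gy"]),
    ("rectum V_40Gy (%)", lambda m: m.per_roi["rectum"]["V_40Gy"]),
    ("rectum D_mean (Gy)", lambda m: m.per_roi["rectum"]["D_mean"]),
    ("bowel bag D_0.03cc (Gy)", lambda m: m.per_roi["bowel bag"]["D_0.03cc"]),
    ("bowel bag V_45Gy (cc)", lambda m: m.per_roi["bowel bag"]["V_45Gy_cc"]),
    ("bowel bag D_mean (Gy)", lambda m: m.per_roi["bowel bag"]["D_mean"]),
    ("femoral head_L V_50Gy (%)", lambda m: m.per_roi["femoral head_L"]["V_50Gy"]),
    ("femoral head_L D_mean (Gy)", lambda m: m.per_roi["femoral head_L"]["D_mean"]),
    ("femoral head_R V_50Gy (%)", lambda m: m.per_roi["femoral head_R"]["V_50Gy"]),
    ("femoral head_R D_mean (Gy)", lambda m: m.per_roi["femoral head_R"]["D_mean"]),
    ("kidney_L D_mean (Gy)", lambda m: m.per_roi["kidney_L"]["D_mean"]),
    ("kidney_R D_mean (Gy)", lambda m: m.per_roi["kidney_R"]["D_mean"]),
    ("GI_40Gy", lambda m: m.gi[40.0]),
    ("GI_30Gy", lambda m: m.gi[30.0]),
    ("GI_20Gy", lambda m: m.gi[20.0]),
    ("GI_10Gy", lambda m: m.gi[10.0]),
]


def metrics_table(metrics: list[PlanMetrics]) -> dict[str, np.ndarray]:
    """Per-metric value vectors across a cohort of evaluated plans."""
    return {label: np.array([fn(m) for m in metrics])
            for label, fn in COMPARISON_METRICS}


def compare_plans(metrics_a: list[PlanMetrics],
                  metrics_b: list[PlanMetrics]) -> list[PairedComparison]:
    """Paired comparison of two planning arms, one row per dosimetric metric."""
    if len(metrics_a) != len(metrics_b):
        raise ValueError("arms must have the same number of (paired) cases")
    ta = metrics_table(metrics_a)
    tb = metrics_table(metrics_b)
    rows = []
    for label in ta:
        va, vb = ta[label], tb[label]
        res = wilcoxon_signed_rank(va, vb)
        rows.append(PairedComparison(
            metric=label,
            mean_a=float(va.mean()), sd_a=float(va.std(ddof=1)) if va.size > 1 else 0.0,
            mean_b=float(vb.mean()), sd_b=float(vb.std(ddof=1)) if vb.size > 1 else 0.0,
            p_value=res.p_value,
            significant=(not res.degenerate) and res.p_value < SIGNIFICANCE_LEVEL,
            degenerate=res.degenerate,
        ))
    return rows


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    n: int
    constant_y: bool = False


def linfit_pearson(x, y) -> RegressionFit:
    """Least-squares line y = slope*x + intercept with the Pearson r.

    Constant x is an error; constant y is flagged with r = 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    sx = x - x.mean()
    sy = y - y.mean()
    sxx = float(sx @ sx)
    if sxx == 0:
        raise ValueError("x is constant; regression undefined")
    sxy = float(sx @ sy)
    syy = float(sy @ sy)
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    if syy == 0:
        return RegressionFit(slope=slope, intercept=intercept, pearson_r=0.0,
                             r_squared=0.0, n=n, constant_y=True)
    r = sxy / np.sqrt(sxx * syy)
    return RegressionFit(slope=slope, intercept=intercept, pearson_r=float(r),
                         r_squared=float(r * r), n=n)


def eud_overlap_regression(overlaps, metrics: list[PlanMetrics],
                           roi: str) -> RegressionFit:
    """Fit the OAR's mean dose (EUD with a = 1) against its PTV overlap.

    ``overlaps`` is the per-case overlap statistic (fraction in [0, 1] for
    bladder/rectum, cc for the bowel bag).
    """
    y = np.array([m.per_roi[roi]["D_mean"] for m in metrics])
    return linfit_pearson(np.asarray(overlaps, float), y)
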