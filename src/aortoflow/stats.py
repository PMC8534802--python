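"""Agreement and comparison statistics: Bland–Altman, Student's test.

The verification workflow compares paired flow measurements (CFD vs.
Doppler-style) with Bland–Altman limits of agreement, and compares groups
with a two-sample Student's t-test preceded by normality (Shapiro–Wilk) and
variance-homogeneity (F-test) checks that select the pooled- or
unequal-variance variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "AgreementResult",
    "TTestReport",
    "bland_altman",
    "students_test",
    "percent_difference",
]


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman summary of paired series a, b (differences d = a - b)."""

    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    diff_span: float
    mean_span: float

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "diff_span": self.diff_span,
            "mean_span": self.mean_span,
        }


def bland_altman(a, b) -> AgreementResult:
    """Limits-of-agreement analysis of two paired measurement series.

    bias = mean(a - b); sd with the n-1 denominator; limits at
    bias +/- 1.96 sd.  ``diff_span`` is max-min of the differences and
    ``mean_span`` max-min of the pair means — both are reported because
    published "range" figures can refer to either.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    m = 0.5 * (a + b)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(
        n=a.size,
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        diff_span=float(d.max() - d.min()),
        mean_span=float(m.max() - m.min()),
    )


@dataclass(frozen=True)
class TTestReport:
    statistic: float
    p_value: float
    variant: str  # "pooled" or "welch"
    normality_p: tuple
    variance_p: float
    notes: str = ""


def students_test(x, y, alpha: float = 0.05) -> TTestReport:
    """Two-sided two-sample t-test with assumption checks.

    Shapiro–Wilk is run on each sample and an F-test on the variance ratio;
    when the variances are compatible (F-test p >= alpha) the pooled-variance
    test is used, otherwise Welch's unequal-variance variant.  Constant
    samples skip the normality check and force the Welch path.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each sample needs at least 3 observations")

    notes = []
    norm_p = []
    degenerate = False
    for label, s in (("x", x), ("y", y)):
        if np.ptp(s) == 0:
            norm_p.append(float("nan"))
            notes.append(f"{label} is constant; normality check skipped")
            degenerate = True
        else:
            norm_p.append(float(sps.shapiro(s).pvalue))

    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 or vy == 0:
        var_p = float("nan")
        equal_var = False
        degenerate = True
    else:
        f = vx / vy
        p_one = sps.f.sf(f, x.size - 1, y.size - 1)
        var_p = float(2.0 * min(p_one, 1.0 - p_one))
        equal_var = var_p >= alpha

    if degenerate:
        equal_var = False
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return TTestReport(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        variant="pooled" if equal_var else "welch",
        normality_p=tuple(norm_p),
        variance_p=var_p,
        notes="; ".join(notes),
    )


def percent_difference(reference: float, value: float) -> float:
    """Signed percentage decrease of ``value`` relative to ``reference``.

    Positive means a decrease (the reporting convention of the study:
    "24% decrease" == percent_difference(ref, 0.76*ref) == 24).
    """
    if reference == 0:
        raise ValueError("reference must be non-zero")
    return 100.0 * (reference - value) / reference
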