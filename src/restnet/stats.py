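"""Cross-subject inference for threshold sweeps.

Paired t-tests of subject metrics against their own null-ensemble
means, Bonferroni-corrected over the threshold grid, plus t-based
confidence intervals for the small-world index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["ThresholdInference", "SwiInterval", "compare_metric_to_null", "swi_interval"]


@dataclass
class ThresholdInference:
    """One row of the per-threshold comparison table."""

    subject_mean: float
    null_mean: float
    t_statistic: float
    p_value: float
    significant_corrected: bool
    alpha: float
    n_tests: int
    zero_variance: bool = False


@dataclass
class SwiInterval:
    lower: float
    upper: float
    mean: float
    level: float
    exceeds_one: bool


def compare_metric_to_null(
    subject_values,
    null_values,
    alpha: float = 0.01,
    n_tests: int = 1,
) -> ThresholdInference:
    """Paired t-test of per-subject metric vs per-subject null-ensemble mean.

    Significance is declared iff p < alpha / n_tests (Bonferroni over
    the active threshold grid).  Zero-variance differences make the
    statistic undefined; the row is flagged instead of significant.
    """
    x = np.asarray(subject_values, dtype=float)
    y = np.asarray(null_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("subject and null value arrays must be paired (equal length)")
    if x.size < 3:
        raise ValueError("need at least 3 subjects")
    diffs = x - y
    if np.allclose(diffs.std(ddof=1), 0.0):
        return ThresholdInference(
            subject_mean=float(x.mean()),
            null_mean=float(y.mean()),
            t_statistic=float("nan"),
            p_value=float("nan"),
            significant_corrected=False,
            alpha=alpha,
            n_tests=n_tests,
            zero_variance=True,
        )
    t, p = sps.ttest_rel(x, y)
    return ThresholdInference(
        subject_mean=float(x.mean()),
        null_mean=float(y.mean()),
        t_statistic=float(t),
        p_value=float(p),
        significant_corrected=bool(p < alpha / n_tests),
        alpha=alpha,
        n_tests=n_tests,
    )


def swi_interval(sigma_values, level: float = 0.99) -> SwiInterval:
    """t-based confidence interval for the mean small-world index.

    ``exceeds_one`` is True iff the lower bound is strictly above 1.
    Constant input degenerates to a zero-width interval at the mean.
    """
    s = np.asarray(sigma_values, dtype=float)
    if s.size < 3:
        raise ValueError("need at least 3 values")
    mean = float(s.mean())
    sem = float(s.std(ddof=1)) / np.sqrt(s.size)
    if sem == 0:
        lower = upper = mean
    else:
        tcrit = sps.t.ppf(0.5 + level / 2.0, df=s.size - 1)
        lower, upper = mean - tcrit * sem, mean + tcrit * sem
    return SwiInterval(
        lower=float(lower), upper=float(upper), mean=mean, level=level, exceeds_one=bool(lower > 1.0)
    )
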