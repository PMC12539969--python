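"""Shared statistical routines.

A single Welch's t implementation is used by both the isotope comparisons
and the shield-length comparisons, so the two report identical numbers for
identical samples by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import UndefinedTestError

__all__ = ["WelchResult", "welch_t", "sample_summary"]


@dataclass(frozen=True)
class WelchResult:
    """Unequal-variance two-sample t-test result.

    Attributes
    ----------
    t : float
        Test statistic ``(mean_x - mean_y) / sqrt(s2x/nx + s2y/ny)``.
    df : float
        Welch–Satterthwaite effective degrees of freedom.
    p : float
        Two-sided p-value from the central t distribution.
    """

    t: float
    df: float
    p: float


def welch_t(x, y) -> WelchResult:
    """Welch's unpaired two-sided t-test.

    Parameters
    ----------
    x, y : array-like
        The two samples; each needs at least two observations and at least
        one of them a positive variance.

    Raises
    ------
    UndefinedTestError
        If a sample has fewer than two values or both variances are zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise UndefinedTestError(
            f"Welch's t needs >=2 observations per sample, got {x.size} and {y.size}"
        )
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise UndefinedTestError("non-finite values in a test sample")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        raise UndefinedTestError("both sample variances are zero; t is undefined")
    res = sps.ttest_ind(x, y, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def sample_summary(values, ddof: int = 1) -> dict:
    """n / mean / sd / min / median / max of a 1-D sample.

    The standard deviation uses the ``n - 1`` denominator and is reported as
    ``nan`` for a single observation rather than raising.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise UndefinedTestError("empty sample")
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=ddof)) if v.size > ddof else float("nan"),
        "min": float(v.min()),
        "median": float(np.median(v)),
        "max": float(v.max()),
    }
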