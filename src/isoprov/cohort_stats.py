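"""Inferential statistics for cohort comparisons.

One-tailed pooled-variance two-sample t-tests (df = n1 + n2 - 2), a
Shapiro-Wilk normality screen for candidate local clusters, and the
radiogenic-Pb outlier discard rule applied before the sex-based Pb
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as _sps

from .baseline import LocalRange
from .samples import IsotopeSample

Direction = Literal["less", "greater"]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_one_tailed: float
    direction: Direction


@dataclass(frozen=True)
class NormalityResult:
    w: float
    p: float


def pooled_t_test(
    group1: Sequence[float], group2: Sequence[float], direction: Direction
) -> TTestResult:
    """Student two-sample t-test with pooled variance, one-tailed.

    ``direction="less"`` tests whether group1's mean is below group2's;
    ``"greater"`` the reverse. Degenerate zero-variance input: equal
    means give the null t = 0, p = 0.5; unequal means are an error (the
    statistic is undefined).
    """
    x = np.asarray(list(group1), dtype=float)
    y = np.asarray(list(group2), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if direction not in ("less", "greater"):
        raise ValueError(f"unknown direction {direction!r}")
    df = len(x) + len(y) - 2
    pooled = ((len(x) - 1) * np.var(x, ddof=1) + (len(y) - 1) * np.var(y, ddof=1)) / df
    if pooled == 0:
        if np.mean(x) == np.mean(y):
            return TTestResult(t=0.0, df=df, p_one_tailed=0.5, direction=direction)
        raise ValueError("zero pooled variance with unequal means: t undefined")
    res = _sps.ttest_ind(x, y, equal_var=True, alternative=direction)
    return TTestResult(
        t=float(res.statistic), df=df,
        p_one_tailed=float(res.pvalue), direction=direction,
    )


def one_tailed_p(t: float, df: int) -> float:
    """Upper-tail Student probability P(T_df > t); the printed (t, df, p)
    triples in site reports can be checked for one-tailed consistency
    with this helper."""
    return float(_sps.t.sf(t, df))


def shapiro_wilk(values: Sequence[float]) -> NormalityResult:
    """Shapiro-Wilk W and p (Royston's approximation, 3 <= n <= 5000).

    Radiogenic isotope ratios in a population exploiting a single dietary
    catchment should be close to normal; a significant result argues
    against treating the group as one catchment.
    """
    arr = np.asarray(list(values), dtype=float)
    if not 3 <= len(arr) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    res = _sps.shapiro(arr)
    return NormalityResult(w=float(res.statistic), p=float(res.pvalue))


def discard_pb_outliers(
    samples: Sequence[IsotopeSample], local: LocalRange
) -> tuple[list[IsotopeSample], list[dict]]:
    """Drop samples whose 206Pb/204Pb exceeds the local Pb maximum.

    A clearly radiogenic Pb signal above the local range marks exposure
    to a different Pb source; such points are removed before sex-based Pb
    comparisons. Returns the retained samples and a discard log naming
    each removal. Samples at the maximum exactly, or missing Pb, are
    retained.
    """
    if "pb206_204" not in local.bounds:
        raise ValueError("local range lacks a pb206_204 axis")
    pb_max = local.bounds["pb206_204"][1]
    kept, log = [], []
    for s in samples:
        if s.pb206_204 is not None and s.pb206_204 > pb_max:
            log.append({
                "sample_id": s.sample_id,
                "reason": f"pb206_204={s.pb206_204} exceeds local max {pb_max}",
            })
        else:
            kept.append(s)
    return kept, log
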