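"""Classical hypothesis tests used for group comparisons.

The statistics (t, χ², F) are computed from their textbook formulas; tail
probabilities come from the regularized incomplete beta/gamma functions via
``scipy.special``.  All tests are two-sided.  No multiple-testing correction
is applied by default — results are flagged significant at a plain α
threshold — but Benjamini–Hochberg adjustment is available for callers that
test many hypotheses at once.

Welch's unequal-variance t-test is the default for independent two-sample
comparisons: with the small group sizes typical of per-sample proportion
comparisons, assuming equal variances buys little and risks much.  Student's
pooled-variance variant is available explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import special

from .errors import ContractError, ZeroVarianceError


@dataclass(slots=True)
class TestResult:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    group_summaries: dict = field(default_factory=dict)

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha

    def as_dict(self) -> dict:
        df = self.df
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "df": df if isinstance(df, (int, float)) else f"{df[0]},{df[1]}",
            "p_value": self.p_value,
        }


def _t_sf_two_sided(t: float, df: float) -> float:
    """Two-sided tail of the t distribution via the regularized beta."""
    return float(2.0 * special.stdtr(df, -abs(t)))


def _check_sample(x: np.ndarray, name: str) -> None:
    if x.size < 2:
        raise ContractError(f"sample {name!r} needs n >= 2 (got {x.size})")
    if not np.all(np.isfinite(x)):
        raise ContractError(f"sample {name!r} contains non-finite values")


def independent_t(
    x: Sequence[float], y: Sequence[float], variant: str = "welch"
) -> TestResult:
    """Two-sample t-test for independent groups.

    ``variant='welch'`` (default) uses per-group variances with the
    Welch–Satterthwaite degrees of freedom; ``'student'`` pools the variance
    with df = n₁+n₂−2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_sample(x, "x")
    _check_sample(y, "y")
    n1, n2 = x.size, y.size
    m1, m2 = x.mean(), y.mean()
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        raise ZeroVarianceError("both samples have zero variance; t undefined")
    if variant == "student":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df: float = n1 + n2 - 2
    elif variant == "welch":
        a, b = v1 / n1, v2 / n2
        se = math.sqrt(a + b)
        df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
    else:
        raise ValueError(f"unknown variant: {variant!r}")
    t = (m1 - m2) / se
    return TestResult(
        test_name=f"independent_t_{variant}",
        statistic=t,
        df=df,
        p_value=_t_sf_two_sided(t, df),
        group_summaries={
            "x": {"n": n1, "mean": m1, "sd": math.sqrt(v1)},
            "y": {"n": n2, "mean": m2, "sd": math.sqrt(v2)},
        },
    )


def paired_t(
    before: Sequence[float],
    after: Sequence[float],
    pairing: Sequence | None = None,
) -> TestResult:
    """Paired t-test on within-pair differences d = after − before.

    The statistic is positive when values increase.  ``pairing`` (e.g.
    patient IDs) exists purely to catch misaligned inputs: it must be
    duplicate-free and the same length as the samples.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.size != a.size:
        raise ContractError(f"paired samples differ in length ({b.size} vs {a.size})")
    if pairing is not None:
        ids = list(pairing)
        if len(ids) != b.size:
            raise ContractError("pairing ids do not match sample length")
        if len(set(ids)) != len(ids):
            raise ContractError("pairing ids contain duplicates")
    _check_sample(b, "before")
    _check_sample(a, "after")
    d = a - b
    n = d.size
    vd = d.var(ddof=1)
    if vd == 0.0:
        if d[0] == 0.0:
            # identical samples: no evidence either way
            return TestResult(
                test_name="paired_t",
                statistic=0.0,
                df=n - 1,
                p_value=1.0,
                group_summaries={"n": n, "mean_diff_after_minus_before": 0.0},
            )
        raise ZeroVarianceError(
            "paired differences are a nonzero constant (zero variance); "
            "the t statistic is undefined"
        )
    t = d.mean() / math.sqrt(vd / n)
    return TestResult(
        test_name="paired_t",
        statistic=t,
        df=n - 1,
        p_value=_t_sf_two_sided(t, n - 1),
        group_summaries={
            "n": n,
            "mean_diff_after_minus_before": float((a - b).mean()),
            "sd_diff": math.sqrt(vd),
        },
    )


def chi_square(table: Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-square test of independence on an r×c contingency table.

    No continuity correction (matching the classical definition);
    df = (r−1)(c−1).  A zero row or column total makes an expected count
    zero and is an error.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ContractError("contingency table must be at least 2x2")
    if np.any(obs < 0):
        raise ContractError("contingency table contains negative counts")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if total == 0 or np.any(row == 0) or np.any(col == 0):
        raise ZeroVarianceError("zero row/column total: expected counts are zero")
    expected = row @ col / total
    stat = float(((obs - expected) ** 2 / expected).sum())
    r, c = obs.shape
    df = (r - 1) * (c - 1)
    return TestResult(
        test_name="chi_square",
        statistic=stat,
        df=df,
        p_value=float(special.chdtrc(df, stat)),
        group_summaries={"observed": obs.tolist(), "expected": expected.tolist()},
    )


def anova_oneway(*groups: Sequence[float]) -> TestResult:
    """One-way fixed-effects ANOVA.

    F = MS_between / MS_within with df (k−1, N−k).  All-constant data (zero
    within-group variance everywhere) is an error; zero between-group sum of
    squares with positive within variance yields F = 0, p = 1.
    """
    if len(groups) < 2:
        raise ContractError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        _check_sample(g, f"group{i}")
    k = len(arrays)
    ns = np.array([g.size for g in arrays])
    n_total = int(ns.sum())
    grand = float(np.concatenate(arrays).mean())
    ss_between = float(sum(n * (g.mean() - grand) ** 2 for n, g in zip(ns, arrays)))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in arrays))
    df1, df2 = k - 1, n_total - k
    if ss_within == 0.0:
        raise ZeroVarianceError("zero within-group variance; F undefined")
    f = (ss_between / df1) / (ss_within / df2)
    return TestResult(
        test_name="anova_oneway",
        statistic=f,
        df=(df1, df2),
        p_value=float(special.fdtrc(df1, df2, f)),
        group_summaries={
            f"group{i}": {"n": int(g.size), "mean": float(g.mean()), "sd": float(g.std(ddof=1))}
            for i, g in enumerate(arrays)
        },
    )


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH step-up adjusted p-values (optional; off by default in pipelines)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running_min = min(running_min, p[idx] * m / rank)
        adjusted[idx] = running_min
    return adjusted.tolist()
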