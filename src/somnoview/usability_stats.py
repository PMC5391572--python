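"""System Usability Scale scoring, benchmark t-test and ICC(3,1).

SUS scoring: odd items contribute (rating - 1), even items (5 - rating);
overall = 2.5 x total contribution (0..100).  The learnability subscale is
items 4 and 8 (x 12.5), usability the remaining eight items (x 3.125), per
the Lewis-Sauro decomposition; the algebraic identity
``overall = 0.8 * usability + 0.2 * learnability`` holds for every response.

ICC(3,1) is the two-way mixed-effects, consistency, single-rater intraclass
correlation: (BMS - EMS) / (BMS + (k-1) EMS), with the exact F-based
confidence bounds of Shrout & Fleiss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SusResponse",
    "SusScores",
    "RatingsMatrix",
    "TestResult",
    "SUS_BENCHMARK_MEAN",
    "SUS_BENCHMARK_SD",
    "LEARNABILITY_ITEMS",
    "score_sus",
    "benchmark_ttest",
    "benchmark_ttest_from_summary",
    "icc31",
    "summarize_study",
]

#: Literature benchmark for an acceptable SUS score.
SUS_BENCHMARK_MEAN = 68.0
SUS_BENCHMARK_SD = 12.5

#: 1-based item numbers forming the learnability subscale.
LEARNABILITY_ITEMS = (4, 8)


@dataclass(frozen=True)
class SusResponse:
    """One respondent's ten 5-point Likert answers."""

    respondent_id: str
    items: tuple  # ten integers in 1..5

    def __post_init__(self) -> None:
        items = tuple(int(i) for i in self.items)
        object.__setattr__(self, "items", items)
        if len(items) != 10:
            raise ValueError(f"SUS response needs exactly 10 items, got {len(items)}")
        for n, v in enumerate(items, start=1):
            if not 1 <= v <= 5:
                raise ValueError(f"item{n} = {v} outside the 1..5 Likert range")


@dataclass(frozen=True)
class SusScores:
    overall: float
    usability: float
    learnability: float


@dataclass(frozen=True)
class RatingsMatrix:
    """Complete n-targets x k-raters matrix of finite ratings."""

    values: np.ndarray
    targets: tuple = ()
    raters: tuple = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("ratings must be a 2-D matrix")
        n, k = values.shape
        if n < 2 or k < 2:
            raise ValueError("ratings matrix needs >= 2 targets and >= 2 raters")
        if not np.all(np.isfinite(values)):
            raise ValueError("ratings matrix must be complete and finite")
        if not self.targets:
            object.__setattr__(self, "targets", tuple(str(i) for i in range(n)))
        if not self.raters:
            object.__setattr__(self, "raters", tuple(str(j) for j in range(k)))
        if len(self.targets) != n or len(self.raters) != k:
            raise ValueError("label lengths do not match matrix shape")

    @property
    def n_targets(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_raters(self) -> int:
        return int(self.values.shape[1])


@dataclass(frozen=True)
class TestResult:
    estimate: float
    ci_low: float
    ci_high: float
    statistic: float
    df: tuple  # (df,) for t; (df1, df2) for F
    p_value: float
    alpha: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("confidence interval must bracket the estimate")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _contributions(response: SusResponse) -> np.ndarray:
    """Per-item contribution in 0..4: odd items rating-1, even items 5-rating."""
    items = np.asarray(response.items, dtype=float)
    out = np.empty(10)
    out[0::2] = items[0::2] - 1  # items 1,3,5,7,9
    out[1::2] = 5 - items[1::2]  # items 2,4,6,8,10
    return out


def score_sus(response: SusResponse) -> SusScores:
    """Transform one response to the 0-100 overall score and the
    learnability (items 4, 8) / usability (remaining 8 items) subscales."""
    c = _contributions(response)
    learn_idx = [i - 1 for i in LEARNABILITY_ITEMS]
    use_idx = [i for i in range(10) if i + 1 not in LEARNABILITY_ITEMS]
    return SusScores(
        overall=float(2.5 * c.sum()),
        usability=float(3.125 * c[use_idx].sum()),
        learnability=float(12.5 * c[learn_idx].sum()),
    )


def benchmark_ttest(
    scores: Sequence[float],
    benchmark: float = SUS_BENCHMARK_MEAN,
    alpha: float = 0.05,
    sides: str = "two",
) -> TestResult:
    """One-sample Student t-test of ``scores`` against a fixed benchmark.

    Uses the sample SD; the benchmark's literature SD is not part of the
    statistic.  The confidence interval is the two-sided (1 - alpha) interval
    for the mean regardless of test sidedness.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("t-test requires at least 2 scores")
    if not np.all(np.isfinite(x)):
        raise ValueError("scores must be finite")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    return benchmark_ttest_from_summary(mean, sd, int(x.size), benchmark, alpha, sides)


def benchmark_ttest_from_summary(
    mean: float,
    sd: float,
    n: int,
    benchmark: float = SUS_BENCHMARK_MEAN,
    alpha: float = 0.05,
    sides: str = "two",
) -> TestResult:
    """Same test computed from printed summary statistics (mean, SD, n)."""
    if n < 2:
        raise ValueError("t-test requires n >= 2")
    if sd <= 0:
        raise ValueError("zero variance: t statistic undefined")
    if sides not in ("two", "greater", "less"):
        raise ValueError("sides must be 'two', 'greater' or 'less'")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n - 1
    se = sd / np.sqrt(n)
    t = (mean - benchmark) / se
    if sides == "two":
        p = 2 * stats.t.sf(abs(t), df)
    elif sides == "greater":
        p = stats.t.sf(t, df)
    else:
        p = stats.t.cdf(t, df)
    half = stats.t.ppf(1 - alpha / 2, df) * se
    return TestResult(
        estimate=mean,
        ci_low=float(mean - half),
        ci_high=float(mean + half),
        statistic=float(t),
        df=(df,),
        p_value=float(min(1.0, p)),
        alpha=alpha,
    )


def icc31(m: RatingsMatrix, alpha: float = 0.05) -> TestResult:
    """ICC(3,1): two-way mixed-effects, consistency, single rater.

    estimate = (BMS - EMS) / (BMS + (k - 1) EMS) where BMS is the
    between-target mean square and EMS the residual mean square of the
    two-way (target x rater) decomposition; CI from the exact F bounds,
    p-value from F = BMS/EMS on (n-1, (n-1)(k-1)) df.
    """
    x = m.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = max(0.0, ss_total - ss_rows - ss_cols)
    df_rows, df_err = n - 1, (n - 1) * (k - 1)
    bms = ss_rows / df_rows
    ems = ss_err / df_err
    if ems <= 1e-12 * max(bms, 1e-300):  # numerically perfect consistency
        ems = 0.0
    if bms == 0 and ems == 0:
        raise ValueError("degenerate ratings matrix: no variance anywhere")
    if ems == 0:
        # perfect consistency: every target ordering identical across raters
        return TestResult(
            estimate=1.0, ci_low=1.0, ci_high=1.0,
            statistic=float("inf"), df=(df_rows, df_err), p_value=0.0, alpha=alpha,
        )
    est = (bms - ems) / (bms + (k - 1) * ems)
    f = bms / ems
    p = float(stats.f.sf(f, df_rows, df_err))
    fl = f / stats.f.ppf(1 - alpha / 2, df_rows, df_err)
    fu = f * stats.f.ppf(1 - alpha / 2, df_err, df_rows)
    ci_low = (fl - 1) / (fl + k - 1)
    ci_high = (fu - 1) / (fu + k - 1)
    return TestResult(
        estimate=float(est),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        statistic=float(f),
        df=(df_rows, df_err),
        p_value=p,
        alpha=alpha,
    )


def summarize_study(
    responses: Sequence[SusResponse],
    benchmark: float = SUS_BENCHMARK_MEAN,
    alpha: float = 0.05,
    ratings: Optional[RatingsMatrix] = None,
) -> pd.DataFrame:
    """Score every respondent and test each scale against the benchmark.

    Returns a table with one row per scale (overall, usability, learnability)
    and columns scale, n, mean, sd, ci_low, ci_high, t, df, p; when a ratings
    matrix is supplied an ICC row is appended (t column holds the F value).
    """
    if len(responses) < 2:
        raise ValueError("study summary requires at least 2 respondents")
    scored = [score_sus(r) for r in responses]
    rows = []
    for scale in ("overall", "usability", "learnability"):
        vals = [getattr(s, scale) for s in scored]
        res = benchmark_ttest(vals, benchmark=benchmark, alpha=alpha)
        rows.append(
            {
                "scale": scale,
                "n": len(vals),
                "mean": res.estimate,
                "sd": float(np.std(vals, ddof=1)),
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "t": res.statistic,
                "df": res.df[0],
                "p": res.p_value,
            }
        )
    if ratings is not None:
        res = icc31(ratings, alpha=alpha)
        rows.append(
            {
                "scale": "icc31",
                "n": ratings.n_targets,
                "mean": res.estimate,
                "sd": float("nan"),
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "t": res.statistic,
                "df": f"{res.df[0]},{res.df[1]}",
                "p": res.p_value,
            }
        )
    return pd.DataFrame(rows)
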