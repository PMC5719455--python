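"""Group-level PRS comparisons and the ancestry–risk relationship.

Two-group PRS distributions are compared with a two-sample t-test (pooled
variance by default, Welch optional); more than two groups with a one-way
ANOVA F-test.  The ancestry–risk relationship is a Pearson correlation of a
chosen ancestry fraction against the PRS with the exact t-transform
p-value, a least-squares trend line, and an equal-count decile-bin summary
of the PRS distribution along the ancestry axis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .popgen import AncestryFractions
from .riskstats import PRSVector

__all__ = [
    "GroupTestResult",
    "AncestryRiskRegression",
    "group_prs_test",
    "ancestry_prs_regression",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupTestResult:
    """t-test (2 groups) or one-way ANOVA (>2 groups) on PRS distributions."""

    test: str  # "t" | "anova"
    statistic: float
    p_value: float
    groups: tuple[str, ...]
    sizes: tuple[int, ...]
    means: tuple[float, ...]
    n_excluded: int = 0  # undefined PRS entries dropped
    degenerate: bool = False  # zero within-group variance


@dataclass
class AncestryRiskRegression:
    """Pearson correlation and linear fit of PRS against an ancestry fraction."""

    pearson_r: float
    p_value: float
    n: int
    slope: float
    intercept: float
    decile_summary: pd.DataFrame  # bin edges and per-bin PRS quartiles

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "n": self.n,
            "slope": self.slope,
            "intercept": self.intercept,
        }


def group_prs_test(
    prs: PRSVector,
    groups: list[str] | None = None,
    welch: bool = False,
) -> GroupTestResult:
    """Compare PRS distributions across population groups.

    Undefined scores are excluded (count reported).  Two groups give a
    two-sample t (pooled variance unless ``welch``); more give a one-way F.
    Zero within-group variance everywhere with differing means is flagged
    degenerate with an infinite statistic and p → 0.
    """
    if prs.populations is None:
        raise ValueError("PRS vector carries no population labels")
    labels = groups if groups is not None else list(dict.fromkeys(prs.populations))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    scores: list[np.ndarray] = []
    n_excluded = 0
    for g in labels:
        idx = [i for i, p in enumerate(prs.populations) if p == g]
        vals = prs.scores[idx]
        ok = ~np.isnan(vals)
        n_excluded += int((~ok).sum())
        vals = vals[ok]
        if vals.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 usable scores")
        scores.append(vals)
    means = tuple(float(v.mean()) for v in scores)
    sizes = tuple(int(v.size) for v in scores)

    if len(labels) == 2:
        pooled_var_zero = all(float(v.var(ddof=1)) == 0.0 for v in scores)
        if pooled_var_zero:
            diff = means[0] - means[1]
            stat = math.inf if diff > 0 else (-math.inf if diff < 0 else 0.0)
            return GroupTestResult(
                "t", stat, 0.0 if diff != 0 else 1.0, tuple(labels), sizes,
                means, n_excluded, degenerate=True,
            )
        res = stats.ttest_ind(scores[0], scores[1], equal_var=not welch)
        return GroupTestResult(
            "t", float(res.statistic), float(res.pvalue), tuple(labels),
            sizes, means, n_excluded,
        )
    res = stats.f_oneway(*scores)
    return GroupTestResult(
        "anova", float(res.statistic), float(res.pvalue), tuple(labels),
        sizes, means, n_excluded,
    )


def _decile_summary(fraction: np.ndarray, score: np.ndarray) -> pd.DataFrame:
    """Equal-count decile bins of the ancestry fraction with PRS quartiles."""
    n = fraction.size
    order = np.argsort(fraction, kind="stable")
    # split sorted samples into 10 near-equal bins (sizes n//10 or n//10+1)
    splits = np.array_split(order, 10)
    rows = []
    for b, idx in enumerate(splits):
        if idx.size == 0:
            continue
        f = fraction[idx]
        s = score[idx]
        rows.append(
            {
                "bin": b + 1,
                "n": idx.size,
                "fraction_low": float(f.min()),
                "fraction_high": float(f.max()),
                "prs_q25": float(np.quantile(s, 0.25)),
                "prs_median": float(np.quantile(s, 0.5)),
                "prs_q75": float(np.quantile(s, 0.75)),
            }
        )
    return pd.DataFrame(rows)


def ancestry_prs_regression(
    fractions: AncestryFractions,
    ancestry_index: int,
    prs: PRSVector,
) -> AncestryRiskRegression:
    """Pearson regression of PRS against one ancestry fraction.

    Samples are matched by ID between the two inputs; undefined scores are
    dropped.  The p-value comes from the exact transform
    ``t = r·sqrt((n−2)/(1−r²))`` with n−2 degrees of freedom (scipy's
    default for a Pearson correlation).
    """
    pos = {s: i for i, s in enumerate(fractions.samples)}
    xs, ys = [], []
    for i, s in enumerate(prs.samples):
        j = pos.get(s)
        if j is None or math.isnan(prs.scores[i]):
            continue
        xs.append(fractions.fractions[j, ancestry_index])
        ys.append(prs.scores[i])
    x = np.asarray(xs)
    y = np.asarray(ys)
    n = x.size
    if n < 10:
        raise ValueError(f"need at least 10 matched samples, have {n}")
    if float(x.var()) == 0.0 or float(y.var()) == 0.0:
        raise ValueError("zero variance in ancestry fraction or PRS")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return AncestryRiskRegression(
        pearson_r=float(r),
        p_value=float(p),
        n=int(n),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        decile_summary=_decile_summary(x, y),
    )
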