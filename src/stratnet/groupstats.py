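"""Descriptive group-comparison battery with Finner correction.

Categorical variables are compared between strata with Pearson's
chi-square (no continuity correction) and Cramér's V; continuous ones
with the pooled-variance Student t-test and Cohen's d. Because the
battery runs one test per variable, the family of raw p-values is
adjusted with Finner's step-down procedure,

    p~_(i) = max_{j <= i} [ 1 - (1 - p_(j))^(m / j) ],

a uniformly less conservative alternative to Bonferroni.

Effect-size interpretation conventions: |V| > 0.20 and |d| > 0.50 flag
mild-moderate-to-large effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .cohort import CohortTable

V_THRESHOLD = 0.20
D_THRESHOLD = 0.50


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    test: str  # "chi_square" | "t_test"
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float
    effect_size: float  # Cramér's V or Cohen's d
    effect_label: str  # "below" | "mild-moderate-large"


def chi_square_test(
    table: np.ndarray,
) -> tuple[float, int, float, float]:
    """Pearson chi-square on an r x c contingency table with Cramér's V.

    No continuity correction. V = sqrt(chi2 / (N * (min(r, c) - 1))).
    Zero row or column margins make expected counts undefined and raise.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if t.sum() <= 0:
        raise ValueError("empty table")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError("zero row/column margin: expected counts undefined")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    v = float(np.sqrt(chi2 / (t.sum() * (min(t.shape) - 1))))
    return float(chi2), int(df), float(p), v


def t_test(
    group_a: np.ndarray, group_b: np.ndarray
) -> tuple[float, int, float, float]:
    """Two-sided pooled-variance Student t-test with Cohen's d.

    d = (mean_a - mean_b) / pooled SD. Groups need n >= 2 each and a
    nonzero pooled variance.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = len(a), len(b)
    df = na + nb - 2
    pooled_var = (
        (na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)
    ) / df
    if pooled_var == 0:
        raise ValueError("zero pooled variance")
    t_stat, p = stats.ttest_ind(a, b, equal_var=True)
    d = float((a.mean() - b.mean()) / np.sqrt(pooled_var))
    return float(t_stat), int(df), float(p), d


def finner_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Finner step-down adjusted p-values, in input order.

    Sort p ascending; p~_(i) = max_{j<=i} [1 - (1-p_(j))^(m/j)]; map back
    and clip to [0, 1]. ``m`` defaults to the family size (the length of
    ``p_values``) and may be larger when the family extends beyond the
    values passed.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-d sequence")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else int(m)
    if m < len(p):
        raise ValueError("family size m cannot be smaller than len(p_values)")
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m / np.arange(1, len(p) + 1))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty_like(p)
    out[order] = np.clip(adj_sorted, 0.0, 1.0)
    return out


def round_percent(count: int, total: int) -> float:
    """Percentage 100*count/total rounded half-up to one decimal."""
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _effect_label(value: float, threshold: float) -> str:
    return "mild-moderate-large" if abs(value) > threshold else "below"


def table_one(cohort: CohortTable) -> dict:
    """Descriptive comparison of the two strata across all variables.

    Binary variables get counts/percentages per column plus a 2x2
    chi-square; continuous variables get mean/SD plus a t-test. Finner
    correction is applied across the whole family in schema order.

    Returns ``{"descriptives": {...}, "comparisons": [ComparisonResult]}``.
    """
    pos = cohort.values[cohort.stratum == 1]
    neg = cohort.values[cohort.stratum == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both strata must be non-empty")

    descriptives: dict[str, dict] = {}
    raw: list[tuple[str, str, float, float, float, float]] = []
    for j, e in enumerate(cohort.schema):
        if e.mtype == "binary":
            # rows = stratum (neg, pos), cols = level (0, 1)
            tab = np.array(
                [
                    [(neg[:, j] == 0).sum(), (neg[:, j] == 1).sum()],
                    [(pos[:, j] == 0).sum(), (pos[:, j] == 1).sum()],
                ]
            )
            chi2, df, p, v = chi_square_test(tab)
            raw.append((e.name, "chi_square", chi2, float(df), p, v))
            descriptives[e.name] = {
                "type": "binary",
                "positive_level": e.positive_level,
                "counts": {
                    "total": int((cohort.values[:, j] == 1).sum()),
                    "negative": int(tab[0, 1]),
                    "positive": int(tab[1, 1]),
                },
                "percent": {
                    "total": round_percent(
                        int((cohort.values[:, j] == 1).sum()), cohort.n
                    ),
                    "negative": round_percent(int(tab[0, 1]), len(neg)),
                    "positive": round_percent(int(tab[1, 1]), len(pos)),
                },
            }
        else:
            t_stat, df, p, d = t_test(pos[:, j], neg[:, j])
            raw.append((e.name, "t_test", t_stat, float(df), p, d))
            descriptives[e.name] = {
                "type": "continuous",
                "mean": {
                    "total": float(cohort.values[:, j].mean()),
                    "negative": float(neg[:, j].mean()),
                    "positive": float(pos[:, j].mean()),
                },
                "sd": {
                    "total": float(cohort.values[:, j].std(ddof=1)),
                    "negative": float(neg[:, j].std(ddof=1)),
                    "positive": float(pos[:, j].std(ddof=1)),
                },
            }

    adjusted = finner_adjust([r[4] for r in raw])
    comparisons = [
        ComparisonResult(
            variable=name,
            test=test,
            statistic=stat,
            df=df,
            p_raw=p,
            p_adjusted=float(p_adj),
            effect_size=eff,
            effect_label=_effect_label(
                eff, V_THRESHOLD if test == "chi_square" else D_THRESHOLD
            ),
        )
        for (name, test, stat, df, p, eff), p_adj in zip(raw, adjusted)
    ]
    return {
        "n": {"total": cohort.n, "negative": len(neg), "positive": len(pos)},
        "descriptives": descriptives,
        "comparisons": comparisons,
    }
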