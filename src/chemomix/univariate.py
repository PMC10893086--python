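"""Two-group per-analyte tests with false-discovery-rate control.

Welch's unequal-variance t-test (Satterthwaite degrees of freedom) and
the Wilcoxon rank-sum test are applied analyte by analyte, two-sided,
and Benjamini–Hochberg adjusted within the table being tested.  Volatile
non-detects are treated as zeros: structural absence in one treatment is
a biologically meaningful difference, and the rank test absorbs the
resulting ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import AnalyteTable, ValidationError

HIGHER_IN_HEAT = "higher_in_heat"
LOWER_IN_HEAT = "lower_in_heat"
NO_DIRECTION = "none"


@dataclass(frozen=True)
class TestResult:
    """Per-analyte two-group test outcome."""

    __test__ = False  # not a pytest collectible despite the name

    analyte_id: str
    layer: str
    test: str  # "welch_t" | "wilcoxon"
    statistic: float
    df: float | None  # Welch only
    p: float
    p_adj: float
    direction: str
    significant: bool


def welch_t_from_summary(
    m1: float, se1: float, n1: int, m2: float, se2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's t from group means, standard errors and sizes.

    t = (m1 - m2) / sqrt(se1^2 + se2^2); the Satterthwaite degrees of
    freedom are (se1^2+se2^2)^2 / (se1^4/(n1-1) + se2^4/(n2-1)); the
    two-sided p comes from Student's t with fractional df.
    """
    if not (se1 > 0 and se2 > 0):
        raise ValidationError("standard errors must be > 0")
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    v1, v2 = se1**2, se2**2
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's t-test from raw samples (se^2 = s^2/n per group)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs >= 2 values")
    s1 = x.std(ddof=1) / np.sqrt(len(x))
    s2 = y.std(ddof=1) / np.sqrt(len(y))
    if s1 == 0 and s2 == 0:
        if x.mean() == y.mean():
            raise ValidationError("zero variance in both groups with equal means")
        # infinite separation: degenerate but directional
        return (np.inf if x.mean() > y.mean() else -np.inf), float(len(x) + len(y) - 2), 0.0
    return welch_t_from_summary(x.mean(), s1, len(x), y.mean(), s2, len(y))


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann–Whitney U) test, two-sided.

    Mid-ranks handle ties.  The p-value is exact (full permutation
    distribution) when n1 + n2 <= 20 and there are no ties, otherwise a
    tie- and continuity-corrected normal approximation is used.
    Returns (U of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValidationError("each group needs >= 1 value")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:  # complete ties
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(combined)) < len(combined)
    method = "asymptotic" if (has_ties or len(combined) > 20) else "exact"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    p = float(res.pvalue)
    if not np.isfinite(p):
        p = 1.0
    return float(res.statistic), min(p, 1.0)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def run_univariate(
    table: AnalyteTable,
    test: str = "welch",
    alpha: float = 0.05,
    nondetect_as_zero: bool = True,
) -> list[TestResult]:
    """Test every analyte for a control-vs-heat difference with BH-FDR.

    The FDR family is the set of analytes actually tested in this table;
    analytes with fewer than two usable values in a group (Welch) are
    skipped with a warning.  Direction follows the sign of the
    heat-minus-control difference of means (Welch) or mean ranks
    (Wilcoxon).
    """
    if test not in ("welch", "wilcoxon"):
        raise ValidationError(f"unknown test {test!r}")
    heat_cols = table.treatment_columns("heat")
    control_cols = table.treatment_columns("control")
    if not heat_cols or not control_cols:
        raise ValidationError("both treatment groups must be present")

    values = table.filled(0.0) if nondetect_as_zero else table.abundance
    rows: list[dict] = []
    for analyte in table.analyte_ids:
        h = values.loc[analyte, heat_cols].dropna().to_numpy(dtype=float)
        c = values.loc[analyte, control_cols].dropna().to_numpy(dtype=float)
        try:
            if test == "welch":
                stat, df, p = welch_t(h, c)
                diff = h.mean() - c.mean()
            else:
                stat, p = wilcoxon_rank_sum(h, c)
                df = None
                ranks = stats.rankdata(np.concatenate([h, c]))
                diff = ranks[: len(h)].mean() - ranks[len(h):].mean()
        except ValidationError as err:
            warnings.warn(f"analyte {analyte!r} skipped: {err}", stacklevel=2)
            continue
        rows.append(
            {"analyte": analyte, "stat": stat, "df": df, "p": p, "diff": diff}
        )

    padj = bh_fdr([r["p"] for r in rows])
    results = []
    for r, q in zip(rows, padj):
        if r["diff"] > 0:
            direction = HIGHER_IN_HEAT
        elif r["diff"] < 0:
            direction = LOWER_IN_HEAT
        else:
            direction = NO_DIRECTION
        results.append(
            TestResult(
                analyte_id=r["analyte"],
                layer=table.layer,
                test="welch_t" if test == "welch" else "wilcoxon",
                statistic=float(r["stat"]),
                df=r["df"],
                p=float(r["p"]),
                p_adj=float(q),
                direction=direction,
                significant=bool(q < alpha),
            )
        )
    return results


def significant_ids(results: list[TestResult]) -> list[str]:
    return [r.analyte_id for r in results if r.significant]
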