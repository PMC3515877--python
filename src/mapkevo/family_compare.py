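"""Family-vs-background comparison of divergence and diversity statistics.

For each statistic (Ka, Ks, Ka/Ks, pi_a, pi_s, pi_a/pi_s) the family is
compared to the genome-wide background by a two-sample Wilcoxon rank-sum
(Mann-Whitney) test, boxplot five-number summaries (whiskers at the most
extreme points within 1.5 IQR of the quartiles), and ordinary
least-squares regression lines of the rate pair (Ka on Ks, or pi_a on
pi_s) for each group.  No multiple-testing correction is applied across
statistics; each is reported individually.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import get_logger

__all__ = [
    "BoxplotSummary",
    "ComparisonReport",
    "fit_regression",
    "wilcoxon_rank_sum",
    "boxplot_summary",
    "compare_family",
]


@dataclass
class BoxplotSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    n: int


@dataclass
class ComparisonReport:
    stat_name: str
    family_summary: BoxplotSummary
    background_summary: BoxplotSummary
    u_statistic: float
    p_value: float
    regression_family: tuple | None = None  # (slope, intercept)
    regression_background: tuple | None = None
    n_excluded_family: int = 0
    n_excluded_background: int = 0


def fit_regression(x_values, y_values) -> tuple:
    """Ordinary least squares of y on x; returns (slope, intercept)."""
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 2:
        raise ValueError("need >= 2 finite pairs")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def wilcoxon_rank_sum(sample_a, sample_b, mode: str = "auto") -> tuple:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) U and two-sided p.

    U is the Mann-Whitney statistic for ``sample_a`` (rank sum minus its
    minimum), midranks for ties.  ``exact`` enumerates the null permutation
    distribution (requires both n <= 12 and no ties); ``normal_approx``
    uses the tie-corrected normal approximation with continuity
    correction; ``auto`` picks exact when permitted.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if mode == "auto":
        mode = "exact" if (len(a) <= 12 and len(b) <= 12 and not has_ties) else "normal_approx"
    if mode == "exact" and has_ties:
        raise ValueError("exact mode requires untied data")
    if mode not in ("exact", "normal_approx"):
        raise ValueError(f"unknown mode {mode!r}")
    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def boxplot_summary(values) -> BoxplotSummary:
    """Median, quartiles (linear interpolation) and 1.5-IQR whiskers clipped
    to observed data."""
    v = np.asarray([x for x in np.asarray(values, dtype=float) if math.isfinite(x)])
    if len(v) == 0:
        raise ValueError("need >= 1 finite value")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return BoxplotSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        n=len(v),
    )


DEFAULT_STATS = ("ka", "ks", "ka_ks")
_REGRESSION_PAIRS = {
    "ka": ("ks", "ka"),
    "ks": ("ks", "ka"),
    "ka_ks": ("ks", "ka"),
    "pi_a": ("pi_s", "pi_a"),
    "pi_s": ("pi_s", "pi_a"),
    "pi_a_pi_s": ("pi_s", "pi_a"),
}


def compare_family(family_table: pd.DataFrame, background_table: pd.DataFrame,
                   stat_list=DEFAULT_STATS) -> list:
    """One ComparisonReport per statistic; family genes are removed from the
    background first.  Genes with non-finite values of a statistic are
    excluded from that statistic only (counts logged and reported).
    """
    if family_table.empty:
        raise ValueError("empty family table")
    background = background_table.drop(
        index=background_table.index.intersection(family_table.index)
    )
    if background.empty:
        raise ValueError("background empty after removing family genes")
    log = get_logger()
    reports = []
    for stat in stat_list:
        fam = family_table[stat].to_numpy(dtype=float)
        bg = background[stat].to_numpy(dtype=float)
        fam_ok = fam[np.isfinite(fam)]
        bg_ok = bg[np.isfinite(bg)]
        n_exc_f, n_exc_b = len(fam) - len(fam_ok), len(bg) - len(bg_ok)
        if n_exc_f or n_exc_b:
            log.info(
                "stat %s: excluded %d family / %d background genes with"
                " undefined values",
                stat, n_exc_f, n_exc_b,
            )
        if len(fam_ok) == 0 or len(bg_ok) == 0:
            raise ValueError(f"stat {stat!r}: no finite values to compare")
        u, p = wilcoxon_rank_sum(fam_ok, bg_ok)
        reg_f = reg_b = None
        pair = _REGRESSION_PAIRS.get(stat)
        if pair and all(c in family_table.columns for c in pair):
            xf, yf = pair
            try:
                reg_f = fit_regression(family_table[xf], family_table[yf])
                reg_b = fit_regression(background[xf], background[yf])
            except ValueError:
                reg_f = reg_b = None
        reports.append(
            ComparisonReport(
                stat_name=stat,
                family_summary=boxplot_summary(fam_ok),
                background_summary=boxplot_summary(bg_ok),
                u_statistic=u,
                p_value=p,
                regression_family=reg_f,
                regression_background=reg_b,
                n_excluded_family=n_exc_f,
                n_excluded_background=n_exc_b,
            )
        )
    return reports
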