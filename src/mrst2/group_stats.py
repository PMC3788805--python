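"""Cohort comparison: Wilcoxon rank-sum tests and summary tables.

T2 distributions are heteroscedastic between groups, so the young and
elderly cohorts are compared nonparametrically with the Wilcoxon
two-sample (Mann-Whitney) rank-sum test, one- and two-sided, at the
p < 0.05 level with no multiple-testing correction.  Summaries report
mean, SD, min and max per group, the elderly/young T2 ratio (2
decimals) and the percent shortening in the elderly (integer percent,
rounded half away from zero).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = ["CohortSummary", "wilcoxon_rank_sum", "summarize_cohorts", "SIGNIFICANCE_LEVEL"]

SIGNIFICANCE_LEVEL = 0.05

_ALTERNATIVES = {"less": "less", "greater": "greater", "two_sided": "two-sided"}


def wilcoxon_rank_sum(x, y, alternative: str = "two_sided") -> float:
    """Wilcoxon rank-sum p-value for samples ``x`` vs ``y``.

    Exact by enumeration when ``n_x + n_y <= 20`` with no ties,
    otherwise the normal approximation with midranks, tie correction
    and continuity correction.  Identical pooled samples return p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {sorted(_ALTERNATIVES)}")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical in both samples; p = 1", RuntimeWarning)
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative=_ALTERNATIVES[alternative], method=method,
                       use_continuity=True)
    return float(res.pvalue)


@dataclass
class CohortSummary:
    """Per-compound group summary (the study's table row analog)."""

    compound: str
    young_mean: float
    young_sd: float
    young_min: float
    young_max: float
    elderly_mean: float
    elderly_sd: float
    elderly_min: float
    elderly_max: float
    p_one_sided: float
    p_two_sided: float
    ratio_elderly_young: float     # rounded to 2 decimals
    pct_shorter: int               # integer percent, round half away from zero
    n_young: int = 0
    n_elderly: int = 0

    @property
    def significant(self) -> bool:
        return self.p_two_sided < SIGNIFICANCE_LEVEL


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def summarize_one(compound: str, young: np.ndarray, elderly: np.ndarray) -> CohortSummary:
    """Summary statistics and rank-sum p-values for one compound."""
    young = np.asarray(young, float)
    elderly = np.asarray(elderly, float)
    if len(young) < 2 or len(elderly) < 2:
        raise ValueError(f"{compound}: need >= 2 subjects per group")
    ratio = float(np.mean(elderly)) / float(np.mean(young))
    return CohortSummary(
        compound=compound,
        young_mean=float(np.mean(young)), young_sd=float(np.std(young, ddof=1)),
        young_min=float(np.min(young)), young_max=float(np.max(young)),
        elderly_mean=float(np.mean(elderly)), elderly_sd=float(np.std(elderly, ddof=1)),
        elderly_min=float(np.min(elderly)), elderly_max=float(np.max(elderly)),
        # one-sided: T2 shorter in elderly, i.e. young stochastically greater
        p_one_sided=wilcoxon_rank_sum(young, elderly, "greater"),
        p_two_sided=wilcoxon_rank_sum(young, elderly, "two_sided"),
        ratio_elderly_young=round(ratio, 2),
        pct_shorter=_round_half_away(100.0 * (1.0 - ratio)),
        n_young=len(young), n_elderly=len(elderly),
    )


def summarize_cohorts(fits: pd.DataFrame) -> pd.DataFrame:
    """Table-style summary for every compound in a per-subject fit table.

    ``fits`` needs columns ``compound``, ``group`` ("young"/"elderly")
    and ``t2``.  Compounds missing one group entirely (or with fewer
    than 2 subjects in a group after fit-failure exclusion) are omitted
    with a warning.  Subject order is irrelevant.
    """
    required = {"compound", "group", "t2"}
    if not required.issubset(fits.columns):
        raise ValueError(f"fit table needs columns {sorted(required)}")
    rows = []
    for compound, sub in fits.groupby("compound", sort=True):
        young = sub.loc[sub["group"] == "young", "t2"].to_numpy()
        elderly = sub.loc[sub["group"] == "elderly", "t2"].to_numpy()
        if len(young) < 2 or len(elderly) < 2:
            warnings.warn(f"compound {compound!r} lacks >= 2 subjects in a group; omitted",
                          RuntimeWarning)
            continue
        rows.append(vars(summarize_one(str(compound), young, elderly)))
    out = pd.DataFrame(rows)
    if not out.empty:
        out["significant"] = out["p_two_sided"] < SIGNIFICANCE_LEVEL
    return out
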