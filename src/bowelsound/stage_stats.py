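"""Stage-wise nonparametric comparison of characteristic values.

Bowel-sound CVs are heavily skewed, so groups are screened for normality
(Lilliefors-corrected Kolmogorov-Smirnov), compared with the
Kruskal-Wallis H omnibus test, and followed up with Dunn's pairwise
z-tests on the pooled ranks with a Bonferroni correction over the ten
stage pairs (the SPSS "pairwise comparisons" procedure). Distributions
are summarized as median (interquartile range).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .audio_io import SLEEP_STAGES

__all__ = [
    "StageGroups",
    "StatsReport",
    "normality_screen",
    "kruskal_wallis",
    "pairwise_posthoc",
    "summarize",
]

StageGroups = Mapping[str, Sequence[float]]


def _clean_groups(groups: StageGroups) -> dict[str, np.ndarray]:
    out = {}
    for stage, vals in groups.items():
        arr = np.asarray(vals, dtype=np.float64)
        arr = arr[np.isfinite(arr)]
        if arr.size:
            out[stage] = arr
    return out


def normality_screen(groups: StageGroups, alpha: float = 0.05) -> pd.DataFrame:
    """Lilliefors-style KS normality p-value per group.

    Groups with fewer than 5 finite values, or with zero variance, are
    flagged untested (NaN p). The ``normal`` column is the decision at
    ``alpha``.
    """
    rows = []
    for stage, vals in _clean_groups(groups).items():
        p = float("nan")
        tested = False
        if vals.size >= 5 and np.ptp(vals) > 0:
            _, p = lilliefors(vals, dist="norm")
            p = float(p)
            tested = True
        rows.append(
            {
                "stage": stage,
                "n": int(vals.size),
                "p": p,
                "tested": tested,
                "normal": bool(tested and p >= alpha),
            }
        )
    return pd.DataFrame(rows)


def kruskal_wallis(groups: StageGroups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction and chi-square p-value.

    Degenerates to (0, 1) when every value across all groups is equal.
    """
    cleaned = _clean_groups(groups)
    if len(cleaned) < 2:
        raise ValueError("need at least two nonempty groups")
    arrays = list(cleaned.values())
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def pairwise_posthoc(
    groups: StageGroups, method: str = "dunn"
) -> pd.DataFrame:
    """Bonferroni-adjusted pairwise p-value matrix over stage pairs.

    ``dunn`` (default) computes z statistics on the pooled tie-corrected
    ranks, the post-hoc SPSS reports after a Kruskal-Wallis test;
    ``mannwhitney`` runs pairwise Mann-Whitney U tests instead. Raw p
    times the number of pairs, capped at 1.
    """
    cleaned = _clean_groups(groups)
    stages = [s for s in SLEEP_STAGES if s in cleaned] + [
        s for s in cleaned if s not in SLEEP_STAGES
    ]
    k = len(stages)
    if k < 2:
        raise ValueError("need at least two nonempty groups")
    n_pairs = k * (k - 1) // 2
    mat = pd.DataFrame(np.full((k, k), np.nan), index=stages, columns=stages)
    np.fill_diagonal(mat.values, 1.0)

    if method == "dunn":
        pooled = np.concatenate([cleaned[s] for s in stages])
        ranks = stats.rankdata(pooled)
        n_total = pooled.size
        mean_ranks = {}
        pos = 0
        for s in stages:
            n_s = cleaned[s].size
            mean_ranks[s] = ranks[pos : pos + n_s].mean()
            pos += n_s
        # tie correction to the rank variance
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var_factor = n_total * (n_total + 1) / 12.0
        if n_total > 1:
            var_factor -= tie_term / (12.0 * (n_total - 1))
        for a, b in combinations(stages, 2):
            na, nb = cleaned[a].size, cleaned[b].size
            se = np.sqrt(var_factor * (1.0 / na + 1.0 / nb))
            if se == 0:
                praw = 1.0
            else:
                z = (mean_ranks[a] - mean_ranks[b]) / se
                praw = 2.0 * stats.norm.sf(abs(z))
            padj = min(1.0, praw * n_pairs)
            mat.loc[a, b] = mat.loc[b, a] = padj
    elif method == "mannwhitney":
        for a, b in combinations(stages, 2):
            xa, xb = cleaned[a], cleaned[b]
            if np.ptp(np.concatenate([xa, xb])) == 0:
                praw = 1.0
            else:
                praw = float(
                    stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue
                )
            mat.loc[a, b] = mat.loc[b, a] = min(1.0, praw * n_pairs)
    else:
        raise ValueError(f"unknown post-hoc method {method!r}")
    return mat


@dataclass
class StatsReport:
    """Stage-wise summary for one characteristic value."""

    cv_name: str
    medians: dict[str, float]
    iqrs: dict[str, float]
    n: dict[str, int]
    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame = field(repr=False)
    normality: pd.DataFrame = field(repr=False)

    def to_markdown(self) -> str:
        stages = list(self.medians)
        lines = [
            f"### {self.cv_name}",
            "| stage | n | median (IQR) |",
            "|---|---|---|",
        ]
        for s in stages:
            lines.append(
                f"| {s} | {self.n[s]} | {self.medians[s]:.4g} ({self.iqrs[s]:.4g}) |"
            )
        lines.append(f"\nKruskal-Wallis H = {self.h_statistic:.3f}, p = {self.p_value:.4g}")
        return "\n".join(lines)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": list(self.medians),
                "n": [self.n[s] for s in self.medians],
                "median": list(self.medians.values()),
                "iqr": list(self.iqrs.values()),
            }
        )


def summarize(groups: StageGroups, cv_name: str) -> StatsReport:
    """Medians, IQRs (linear-interpolation quantiles), omnibus test and
    Bonferroni-adjusted pairwise matrix for one CV."""
    cleaned = _clean_groups(groups)
    if not cleaned:
        raise ValueError("no nonempty groups")
    stages = [s for s in SLEEP_STAGES if s in cleaned] + [
        s for s in cleaned if s not in SLEEP_STAGES
    ]
    medians = {s: float(np.median(cleaned[s])) for s in stages}
    iqrs = {
        s: float(np.percentile(cleaned[s], 75) - np.percentile(cleaned[s], 25))
        for s in stages
    }
    ns = {s: int(cleaned[s].size) for s in stages}
    if len(stages) >= 2:
        h, p = kruskal_wallis(cleaned)
        pairwise = pairwise_posthoc(cleaned)
    else:
        h, p = float("nan"), float("nan")
        only = stages[0]
        pairwise = pd.DataFrame([[1.0]], index=[only], columns=[only])
    normality = normality_screen(cleaned)
    return StatsReport(
        cv_name=cv_name,
        medians=medians,
        iqrs=iqrs,
        n=ns,
        h_statistic=h,
        p_value=p,
        pairwise=pairwise,
        normality=normality,
    )
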