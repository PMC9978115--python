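"""Normality-gated pairwise group comparisons with Bonferroni correction.

The comparison machinery mirrors common practice for small-n MEA studies
(5–6 networks per condition): each metric at each timepoint is tested for
normality per group with the Shapiro-Wilk test; if every group passes
(p >= 0.05), pairwise Welch's unequal-variance t-tests are used, otherwise
the rank-based Conover-Iman pairwise test computed on joint ranks with the
Kruskal-Wallis tie-corrected statistic.  Raw p-values are Bonferroni
corrected over the family of all pairwise comparisons within one
metric-timepoint (the `pairs` family); correcting additionally across
timepoints is available via ``family="all"``.

The Conover-Iman statistic for groups a, b on joint ranks R is

    t = (Rbar_a - Rbar_b) / sqrt(S^2 * (N - 1 - H) / (N - k) * (1/n_a + 1/n_b))

with S^2 = (sum R_i^2 - N (N+1)^2 / 4) / (N - 1), H the tie-corrected
Kruskal-Wallis statistic, N total observations and k groups; t is referred
to a Student t distribution with N - k degrees of freedom (two-sided).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonResult",
    "normality_gate",
    "welch_t",
    "conover_pairwise",
    "pairwise_compare",
    "compare_table",
    "type_i_calibration",
]

NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    timepoint: str
    group_a: str
    group_b: str
    test_used: str  # "welch" | "conover"
    statistic: float
    p_raw: float
    p_adjusted: float
    n_a: int
    n_b: int
    normality_p: dict[str, float]

    @property
    def significant(self) -> bool:
        return self.p_adjusted < 0.05


def normality_gate(
    groups: dict[str, np.ndarray], alpha: float = NORMALITY_ALPHA
) -> tuple[bool, dict[str, float]]:
    """Shapiro-Wilk gate: normal iff every group's p >= alpha.

    Groups with fewer than 3 observations cannot be tested and force the
    non-normal branch (with a warning); their p is reported as nan.
    """
    pvals: dict[str, float] = {}
    all_normal = True
    for label, values in groups.items():
        values = np.asarray(values, dtype=float)
        if values.size < 3:
            warnings.warn(
                f"group {label!r} has n={values.size} < 3; "
                "normality untestable, using rank-based branch",
                stacklevel=2,
            )
            pvals[label] = float("nan")
            all_normal = False
            continue
        if np.ptp(values) == 0:
            # constant group: Shapiro undefined; clearly not usable as normal
            pvals[label] = 0.0
            all_normal = False
            continue
        p = float(stats.shapiro(values).pvalue)
        pvals[label] = p
        if p < alpha:
            all_normal = False
    return all_normal, pvals


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance two-sided t-test: (statistic, p)."""
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def conover_pairwise(
    groups: dict[str, np.ndarray],
    pair: tuple[str, str],
) -> tuple[float, float]:
    """Conover-Iman rank test for one pair, in the context of all groups.

    Joint ranks are computed over *all* groups; the variance estimate and
    the degrees of freedom use the full layout, as in the standard
    Kruskal-Wallis post-hoc formulation.  Returns (statistic, two-sided p).
    """
    labels = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in labels]
    all_vals = np.concatenate(values)
    n_total = all_vals.size
    k = len(labels)
    if n_total <= k:
        raise ValueError("need more observations than groups")

    ranks = stats.rankdata(all_vals)
    rank_groups: dict[str, np.ndarray] = {}
    pos = 0
    for g, v in zip(labels, values):
        rank_groups[g] = ranks[pos : pos + v.size]
        pos += v.size

    if np.ptp(all_vals) == 0:
        return 0.0, 1.0  # all observations identical: no evidence

    h = _kruskal_h(list(rank_groups.values()), n_total)
    s2 = (np.sum(ranks**2) - n_total * (n_total + 1) ** 2 / 4) / (n_total - 1)

    a, b = pair
    ra, rb = rank_groups[a], rank_groups[b]
    num = ra.mean() - rb.mean()
    denom_sq = s2 * ((n_total - 1 - h) / (n_total - k)) * (
        1 / ra.size + 1 / rb.size
    )
    if denom_sq <= 0:
        # perfect separation of every group by rank: maximal evidence
        return float(np.sign(num) * np.inf), 0.0
    t = num / np.sqrt(denom_sq)
    p = 2 * stats.t.sf(abs(t), df=n_total - k)
    return float(t), float(min(p, 1.0))


def _kruskal_h(rank_groups: list[np.ndarray], n_total: int) -> float:
    """Tie-corrected Kruskal-Wallis H from pre-computed joint ranks."""
    h = (
        12 / (n_total * (n_total + 1))
        * sum(rg.sum() ** 2 / rg.size for rg in rank_groups)
        - 3 * (n_total + 1)
    )
    all_ranks = np.concatenate(rank_groups)
    _, counts = np.unique(all_ranks, return_counts=True)
    tie_term = 1 - np.sum(counts**3 - counts) / (n_total**3 - n_total)
    return h / tie_term if tie_term > 0 else 0.0


def pairwise_compare(
    groups: dict[str, np.ndarray],
    metric: str = "",
    timepoint: str = "",
    alpha: float = 0.05,
    family_size: int | None = None,
) -> list[ComparisonResult]:
    """Compare all unordered group pairs with the normality-gated test.

    Bonferroni family size defaults to the number of pairs, C(k, 2);
    ``family_size`` overrides it for wider families.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} needs >= 2 observations")

    all_normal, norm_p = normality_gate(groups)
    pairs = list(itertools.combinations(sorted(groups), 2))
    m = family_size if family_size is not None else len(pairs)

    results = []
    for a, b in pairs:
        va, vb = groups[a], groups[b]
        degenerate = np.ptp(va) == 0 and np.ptp(vb) == 0
        if degenerate and va[0] == vb[0]:
            stat, p_raw = 0.0, 1.0
            test = "degenerate"
        elif all_normal:
            stat, p_raw = welch_t(va, vb)
            test = "welch"
        else:
            stat, p_raw = conover_pairwise(groups, (a, b))
            test = "conover"
        results.append(
            ComparisonResult(
                metric=metric,
                timepoint=timepoint,
                group_a=a,
                group_b=b,
                test_used=test,
                statistic=stat,
                p_raw=p_raw,
                p_adjusted=min(1.0, p_raw * m),
                n_a=va.size,
                n_b=vb.size,
                normality_p=norm_p,
            )
        )
    return results


def compare_table(
    table: pd.DataFrame,
    alpha: float = 0.05,
    family: str = "pairs",
) -> pd.DataFrame:
    """Run pairwise comparisons for every (metric, timepoint) of a long table.

    ``table`` columns: recording_id, group, timepoint, metric, value.
    ``family="pairs"`` corrects within each metric-timepoint;
    ``family="all"`` corrects over all comparisons of one metric across its
    timepoints as well.
    """
    required = {"group", "timepoint", "metric", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"metric table missing columns {sorted(missing)}")

    rows = []
    for (metric, timepoint), sub in table.groupby(
        ["metric", "timepoint"], sort=True
    ):
        sub = sub.dropna(subset=["value"])
        groups = {
            str(g): v["value"].to_numpy()
            for g, v in sub.groupby("group")
            if len(v) >= 2
        }
        if len(groups) < 2:
            continue
        n_pairs = len(groups) * (len(groups) - 1) // 2
        if family == "all":
            n_tp = table.loc[table["metric"] == metric, "timepoint"].nunique()
            fam = n_pairs * n_tp
        else:
            fam = n_pairs
        for r in pairwise_compare(
            groups, metric=str(metric), timepoint=str(timepoint),
            alpha=alpha, family_size=fam,
        ):
            rows.append(
                {
                    "metric": r.metric,
                    "timepoint": r.timepoint,
                    "group_a": r.group_a,
                    "group_b": r.group_b,
                    "test_used": r.test_used,
                    "statistic": r.statistic,
                    "p_raw": r.p_raw,
                    "p_adjusted": r.p_adjusted,
                    "n_a": r.n_a,
                    "n_b": r.n_b,
                    "significant": r.p_adjusted < alpha,
                }
            )
    cols = [
        "metric", "timepoint", "group_a", "group_b", "test_used",
        "statistic", "p_raw", "p_adjusted", "n_a", "n_b", "significant",
    ]
    return pd.DataFrame(rows, columns=cols)


def type_i_calibration(
    n_groups: int = 3,
    n_per_group: int = 6,
    reps: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Family-wise false-rejection rate under an identical-groups null.

    Draws ``n_groups`` standard-normal samples of ``n_per_group`` per rep,
    runs the gated pairwise comparison, and returns the fraction of families
    with at least one Bonferroni-adjusted rejection.  With a valid gate and
    Bonferroni correction the rate should not exceed ``alpha`` by more than
    Monte-Carlo error.
    """
    rng = np.random.default_rng(seed)
    n_reject = 0
    labels = [f"g{i}" for i in range(n_groups)]
    for _ in range(reps):
        groups = {g: rng.standard_normal(n_per_group) for g in labels}
        results = pairwise_compare(groups, alpha=alpha)
        if any(r.p_adjusted < alpha for r in results):
            n_reject += 1
    return n_reject / reps
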