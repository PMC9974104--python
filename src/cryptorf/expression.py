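"""Two-group differential expression, survival association, set overlap.

Implements the expression-side filters of the triage: tumor-vs-normal
(or knockout-vs-control) differential expression with BH-FDR, printed
threshold selection with exact boundary semantics (log2FC inclusive,
FDR strict), a median-split log-rank survival association, and Fisher
exact set-overlap tests with an explicitly supplied universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import InputError, get_logger

log = get_logger("expression")


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone in p-rank)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# differential expression


def differential_expression(
    matrix: pd.DataFrame,
    group_labels: pd.Series,
    groups: tuple[str, str] | None = None,
    test: str = "wilcoxon",
    log_transform: bool = False,
) -> pd.DataFrame:
    """Per-gene two-group contrast: lfc (group2 - group1), p, and BH-FDR.

    ``matrix`` is genes x samples on the log2 scale (set ``log_transform``
    for raw values, which are log2(x+1)-transformed first). The default
    test is the two-sided Wilcoxon rank-sum; ``test="welch"`` selects the
    unequal-variance t-test. Genes constant across all samples get p = 1
    by convention and are flagged in the ``constant`` column.
    """
    if groups is None:
        uniq = sorted(group_labels.unique())
        if len(uniq) != 2:
            raise InputError(f"expected exactly 2 groups, found {uniq}")
        groups = (uniq[0], uniq[1])
    g1, g2 = groups
    cols1 = group_labels.index[group_labels == g1]
    cols2 = group_labels.index[group_labels == g2]
    if len(cols1) < 2 or len(cols2) < 2:
        raise InputError("each group needs at least 2 samples")
    if test not in ("wilcoxon", "welch"):
        raise InputError(f"unknown test: {test}")

    data = matrix[list(cols1) + list(cols2)]
    if log_transform:
        data = np.log2(data + 1.0)
    a = data[cols1].to_numpy(dtype=float)
    b = data[cols2].to_numpy(dtype=float)
    lfc = b.mean(axis=1) - a.mean(axis=1)

    constant = np.array([np.ptp(row) == 0 for row in data.to_numpy(dtype=float)])
    p = np.ones(len(data))
    var_rows = ~constant
    if var_rows.any():
        if test == "wilcoxon":
            res = stats.mannwhitneyu(
                a[var_rows], b[var_rows], axis=1, alternative="two-sided"
            )
        else:
            res = stats.ttest_ind(a[var_rows], b[var_rows], axis=1, equal_var=False)
        p[var_rows] = res.pvalue
    if constant.any():
        log.warning("%d constant genes assigned p = 1", int(constant.sum()))

    return pd.DataFrame(
        {
            "gene_id": data.index,
            "lfc": lfc,
            "p_value": p,
            "fdr": bh_adjust(p),
            "constant": constant,
        }
    ).set_index("gene_id")


def select_genes(
    de_results: pd.DataFrame,
    lfc_min: float,
    fdr_max: float,
    direction: str = "up",
) -> set[str]:
    """Threshold selection with printed boundary semantics: lfc >= (inclusive),
    FDR < (strict). ``direction`` is up, down, or both (|lfc| >= lfc_min)."""
    if direction not in ("up", "down", "both"):
        raise InputError(f"direction must be up/down/both, got {direction}")
    lfc = de_results["lfc"]
    if direction == "up":
        pass_lfc = lfc >= lfc_min
    elif direction == "down":
        pass_lfc = lfc <= -lfc_min
    else:
        pass_lfc = lfc.abs() >= lfc_min
    mask = pass_lfc & (de_results["fdr"] < fdr_max)
    return set(de_results.index[mask])


# ---------------------------------------------------------------------------
# survival


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    n_high: int
    n_low: int
    sum_o_minus_e: float  # observed-minus-expected events in the high stratum


def logrank_test(
    time: np.ndarray, event: np.ndarray, in_group1: np.ndarray
) -> tuple[float, float, float]:
    """Two-group log-rank: ((sum O-E)^2 / sum V, p from chi2_1, sum O-E).

    O-E and the hypergeometric variance V are accumulated over distinct
    event times; V is zero when only one subject remains at risk.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    g1 = np.asarray(in_group1, dtype=bool)
    if event.sum() < 1:
        raise InputError("log-rank needs at least one observed event")

    oe = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & g1).sum())
        oe += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0.0:
        return 0.0, 1.0, oe
    statistic = oe * oe / var
    return float(statistic), float(stats.chi2.sf(statistic, df=1)), float(oe)


def logrank_by_expression(
    survival: pd.DataFrame,
    expression_vector: pd.Series,
    split: str | float = "median",
) -> LogrankResult:
    """Median-split (or fixed-cut) log-rank association of survival with
    one gene's expression. High stratum: expression >= cut.

    ``survival`` needs sample_id, time, event; samples are matched to
    ``expression_vector`` by sample_id.
    """
    sv = survival.set_index("sample_id")
    common = sv.index.intersection(expression_vector.index)
    if len(common) < len(sv):
        log.warning("%d survival samples lack expression and were dropped",
                    len(sv) - len(common))
    sv = sv.loc[common]
    expr = expression_vector.loc[common]
    cut = float(expr.median()) if split == "median" else float(split)
    high = (expr >= cut).to_numpy()
    if high.all() or not high.any():
        raise InputError(
            "expression split produced an empty stratum; choose a different split"
        )
    stat, p, oe = logrank_test(sv["time"].to_numpy(), sv["event"].to_numpy(), high)
    return LogrankResult(
        statistic=stat,
        p_value=p,
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
        sum_o_minus_e=oe,
    )


# ---------------------------------------------------------------------------
# set overlap


@dataclass
class OverlapResult:
    both: int
    a_only: int
    b_only: int
    neither: int
    odds_ratio: float
    p_value: float
    alternative: str

    @property
    def table(self) -> list[list[int]]:
        return [[self.both, self.a_only], [self.b_only, self.neither]]


def fisher_overlap(
    set_a: set, set_b: set, universe: set, alternative: str = "two-sided"
) -> OverlapResult:
    """Fisher exact test on the 2x2 membership table of two sets.

    The universe must be supplied explicitly and contain both sets; the
    odds ratio uses a 0.5 Haldane correction when any cell is zero.
    """
    offenders = (set_a | set_b) - universe
    if offenders:
        raise InputError(f"elements outside universe: {sorted(offenders)[:10]}")
    both = len(set_a & set_b)
    a_only = len(set_a - set_b)
    b_only = len(set_b - set_a)
    neither = len(universe) - both - a_only - b_only
    table = [[both, a_only], [b_only, neither]]
    _, p = stats.fisher_exact(table, alternative=alternative)
    if min(both, a_only, b_only, neither) == 0:
        odds = ((both + 0.5) * (neither + 0.5)) / ((a_only + 0.5) * (b_only + 0.5))
    else:
        odds = (both * neither) / (a_only * b_only)
    return OverlapResult(
        both=both,
        a_only=a_only,
        b_only=b_only,
        neither=neither,
        odds_ratio=float(odds),
        p_value=float(p),
        alternative=alternative,
    )
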