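"""CRISPR screen analysis: normalization, per-guide statistics, hit calls.

Per-guide depletion significance is an empirical one-sided tail against
the negative-control log2FC distribution with a +1 correction — the
library's negative controls are the assumption-free null. An ORF is a
hit when at least ``min_sgrnas`` of its guides are significantly
depleted at the printed thresholds (lfc <= -log2(1.5) inclusive,
p < 0.05 strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import ConfigError, InputError, get_logger

log = get_logger("screen")

DEFAULT_LFC_THRESHOLD = -float(np.log2(1.5))
DEFAULT_P_THRESHOLD = 0.05
DEFAULT_MIN_SGRNAS = 2

CLASSES = ("targeting", "positive_control", "negative_control")


def _check_library(library: pd.DataFrame) -> pd.DataFrame:
    lib = library.set_index("sgrna_id") if "sgrna_id" in library.columns else library
    bad = set(lib["class"]) - set(CLASSES)
    if bad:
        raise InputError(f"unknown sgRNA classes: {sorted(bad)}")
    targeting = lib["class"] == "targeting"
    if (targeting & lib["target_orf_id"].isna()).any():
        raise InputError("targeting sgRNAs must carry a target_orf_id")
    return lib


# ---------------------------------------------------------------------------
# normalization


def normalize_counts(
    counts: pd.DataFrame,
    library: pd.DataFrame,
    method: str = "control-median",
) -> tuple[pd.DataFrame, pd.Series]:
    """Scale samples to a common reference; returns (normalized, size_factors).

    control-median: each sample is divided by (its median negative-control
    count / geometric mean of those medians across samples), so after
    normalization every sample has the same negative-control median.
    total: same construction on per-sample totals.
    """
    if (counts < 0).any().any():
        raise InputError("counts must be non-negative")
    zero_samples = counts.columns[(counts.sum(axis=0) == 0)]
    if len(zero_samples):
        raise InputError(f"all-zero sample(s): {list(zero_samples)}")
    lib = _check_library(library)

    if method == "control-median":
        neg = lib.index[lib["class"] == "negative_control"]
        neg = counts.index.intersection(neg)
        if len(neg) == 0:
            raise InputError("control-median normalization needs >=1 negative control")
        ref = counts.loc[neg].median(axis=0)
    elif method == "total":
        ref = counts.sum(axis=0)
    else:
        raise ConfigError(f"unknown normalization method: {method}")
    if (ref <= 0).any():
        raise InputError("normalization reference is zero for some sample")
    geo_mean = float(np.exp(np.log(ref).mean()))
    size_factors = ref / geo_mean
    return counts / size_factors, size_factors


# ---------------------------------------------------------------------------
# per-guide statistics


def sgrna_stats(
    norm_counts: pd.DataFrame,
    library: pd.DataFrame,
    pseudocount: float = 1.0,
    replicate_policy: str = "mean",
) -> pd.DataFrame:
    """Per-guide log2FC (day21 vs day0) and empirical depletion p-value.

    lfc = log2((mean day21 + pseudocount) / (mean day0 + pseudocount)).
    p = (1 + #{negative-control lfcs <= observed}) / (1 + #negative
    controls): the +1-corrected, tie-inclusive rank in the control null.
    """
    if replicate_policy != "mean":
        raise ConfigError(f"unknown replicate_policy: {replicate_policy}")
    lib = _check_library(library)
    day0 = [c for c in norm_counts.columns if c.startswith("day0")]
    day21 = [c for c in norm_counts.columns if c.startswith("day21")]
    if not day0 or not day21:
        raise InputError("both day0* and day21* sample columns are required")

    m0 = norm_counts[day0].mean(axis=1)
    m21 = norm_counts[day21].mean(axis=1)
    lfc = np.log2((m21 + pseudocount) / (m0 + pseudocount))

    neg_ids = lib.index[lib["class"] == "negative_control"]
    neg_ids = lfc.index.intersection(neg_ids)
    if len(neg_ids) == 0:
        raise InputError("empirical p-values need >=1 negative control sgRNA")
    neg_sorted = np.sort(lfc.loc[neg_ids].to_numpy())
    m = len(neg_sorted)
    # tie-inclusive count of controls <= observed
    ranks = np.searchsorted(neg_sorted, lfc.to_numpy(), side="right")
    p = (1.0 + ranks) / (1.0 + m)

    out = pd.DataFrame({"lfc": lfc, "p_value": p})
    out["class"] = lib["class"]
    out["target_orf_id"] = lib["target_orf_id"]
    return out


# ---------------------------------------------------------------------------
# hit calling


@dataclass
class OrfHit:
    orf_id: str
    n_sig_depleted: int
    n_sgrnas: int
    is_hit: bool


def call_hits(
    stats_df: pd.DataFrame,
    library: pd.DataFrame,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    min_sgrnas: int = DEFAULT_MIN_SGRNAS,
) -> pd.DataFrame:
    """ORF-level hit calls: a guide is significantly depleted iff
    lfc <= lfc_threshold (inclusive) and p < p_threshold (strict); an ORF
    is a hit iff at least ``min_sgrnas`` of its guides pass both."""
    lib = _check_library(library)
    targeting = lib[lib["class"] == "targeting"]
    merged = targeting.join(stats_df[["lfc", "p_value"]], how="left")
    missing = merged["lfc"].isna()
    if missing.any():
        log.warning("%d targeting sgRNAs missing from stats", int(missing.sum()))
    sig = (merged["lfc"] <= lfc_threshold) & (merged["p_value"] < p_threshold)
    per_orf = (
        merged.assign(sig=sig.fillna(False))
        .groupby("target_orf_id", sort=True)
        .agg(n_sig_depleted=("sig", "sum"), n_sgrnas=("sig", "size"))
        .reset_index()
        .rename(columns={"target_orf_id": "orf_id"})
    )
    zero_guides = per_orf["n_sgrnas"] == 0
    if zero_guides.any():
        log.warning("%d ORFs had zero targeting sgRNAs in stats", int(zero_guides.sum()))
    per_orf["is_hit"] = per_orf["n_sig_depleted"] >= min_sgrnas
    return per_orf.set_index("orf_id")


# ---------------------------------------------------------------------------
# positive-control QC


@dataclass
class ScreenQc:
    median_lfc: dict[str, float]
    rank_sum_p: float | None
    passed: bool | None  # None when not evaluable

    def to_dict(self) -> dict:
        return {
            "median_lfc_by_class": self.median_lfc,
            "positive_vs_negative_rank_sum_p": self.rank_sum_p,
            "passed": self.passed,
        }


def positive_control_qc(
    stats_df: pd.DataFrame, library: pd.DataFrame, alpha: float = 0.01
) -> ScreenQc:
    """Check that positive-control guides deplete relative to negatives:
    per-class median lfc plus a one-sided rank-sum test (positive < negative)."""
    lib = _check_library(library)
    joined = stats_df.drop(columns=["class"], errors="ignore").join(
        lib["class"], how="inner"
    )
    medians = {
        cls: float(joined.loc[joined["class"] == cls, "lfc"].median())
        for cls in CLASSES
        if (joined["class"] == cls).any()
    }
    pos = joined.loc[joined["class"] == "positive_control", "lfc"]
    neg = joined.loc[joined["class"] == "negative_control", "lfc"]
    if pos.empty or neg.empty:
        log.warning("positive-control QC not evaluable: a control class is empty")
        return ScreenQc(median_lfc=medians, rank_sum_p=None, passed=None)
    res = stats.mannwhitneyu(pos, neg, alternative="less")
    p = float(res.pvalue)
    return ScreenQc(median_lfc=medians, rank_sum_p=p, passed=bool(p < alpha))
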