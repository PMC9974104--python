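"""Peak annotation, common-peak intersection, TSS-window assignment, triage.

The final nomination step of the analysis: genes must be co-upregulated
by both factors, tumor-upregulated, harbor at least one common binding
site within a strand-aware -30 kb/+10 kb window around the TSS, and show
a gene-effect score below -0.2 (strict) in every required cell line.

All intervals are 0-based half-open; peak "overlap" means >= 1 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import ConfigError, InputError, get_logger

log = get_logger("regulatory")

DEFAULT_UPSTREAM = 30_000
DEFAULT_DOWNSTREAM = 10_000
DEFAULT_EFFECT_THRESHOLD = -0.2
DEFAULT_MARGIN = 3_000

CATEGORIES = ("promoter_proximal", "tts_proximal", "exonic", "intronic",
              "distal_intergenic", "unplaced")


# ---------------------------------------------------------------------------
# category annotation


def annotate_peak_category(
    peaks: pd.DataFrame, gene_models: pd.DataFrame, margin: int = DEFAULT_MARGIN
) -> pd.Series:
    """One genomic category per peak, decided at the peak midpoint.

    Precedence: promoter-proximal (<= margin of a TSS) > TTS-proximal
    (<= margin of a TTS) > exonic > intronic > distal intergenic. Peaks
    on chromosomes absent from the gene models are "unplaced".
    """
    cats = []
    gm_by_chrom = dict(tuple(gene_models.groupby("chrom")))
    for _, peak in peaks.iterrows():
        mid = (int(peak["start"]) + int(peak["end"])) // 2
        gm = gm_by_chrom.get(peak["chrom"])
        if gm is None:
            log.warning("peak on unknown chromosome %s", peak["chrom"])
            cats.append("unplaced")
            continue
        tss_d = (gm["tss"] - mid).abs().min()
        tts_d = (gm["tts"] - mid).abs().min()
        if tss_d <= margin:
            cats.append("promoter_proximal")
            continue
        if tts_d <= margin:
            cats.append("tts_proximal")
            continue
        in_gene = (gm["start"] <= mid) & (mid < gm["end"])
        if in_gene.any():
            exonic = False
            for _, g in gm[in_gene].iterrows():
                for ex_start, ex_end in g.get("exons") or ():
                    if ex_start <= mid < ex_end:
                        exonic = True
                        break
            cats.append("exonic" if exonic else "intronic")
        else:
            cats.append("distal_intergenic")
    return pd.Series(cats, index=peaks.index, name="category")


# ---------------------------------------------------------------------------
# interval intersection


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Union of [start, end) intervals, sorted and merged."""
    if len(iv) == 0:
        return iv.reshape(0, 2)
    iv = iv[np.argsort(iv[:, 0])]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out)


def _intersect_two(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Coordinate intersection of two merged interval arrays."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append([lo, hi])
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return np.array(out) if out else np.empty((0, 2), dtype=int)


def intersect_peak_sets(peak_sets: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Maximal intervals covered by >= 1 peak in EVERY input set.

    Input sets are BED-style frames (chrom, start, end); the result is
    the per-chromosome coordinate intersection of their merged unions.
    """
    if len(peak_sets) < 2:
        raise InputError("need at least 2 peak sets to intersect")
    for k, ps in enumerate(peak_sets):
        if ps.empty:
            log.warning("peak set %d is empty: common set is empty", k)
            return pd.DataFrame(columns=["chrom", "start", "end"])
    chroms = set.intersection(*(set(ps["chrom"]) for ps in peak_sets))
    rows = []
    for chrom in sorted(chroms):
        merged = [
            _merge_intervals(ps.loc[ps["chrom"] == chrom, ["start", "end"]].to_numpy())
            for ps in peak_sets
        ]
        common = merged[0]
        for nxt in merged[1:]:
            common = _intersect_two(common, nxt)
            if len(common) == 0:
                break
        rows.extend({"chrom": chrom, "start": int(s), "end": int(e)} for s, e in common)
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def peaks_overlapping(peaks: pd.DataFrame, regions: pd.DataFrame) -> pd.Series:
    """Boolean per peak: overlaps (>= 1 bp) any region. Used for Venn-style
    counts of peaks shared with a common set."""
    flags = np.zeros(len(peaks), dtype=bool)
    by_chrom = dict(tuple(regions.groupby("chrom"))) if not regions.empty else {}
    for i, (_, peak) in enumerate(peaks.iterrows()):
        reg = by_chrom.get(peak["chrom"])
        if reg is None:
            continue
        flags[i] = bool(
            ((reg["start"] < peak["end"]) & (peak["start"] < reg["end"])).any()
        )
    return pd.Series(flags, index=peaks.index, name="shared")


# ---------------------------------------------------------------------------
# window assignment


def gene_window(
    tss: int,
    strand: str,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    strand_aware: bool = True,
) -> tuple[int, int]:
    """Strand-aware regulatory window around a TSS as a half-open interval.

    On + genes the window is [tss - upstream, tss + downstream); on -
    genes upstream extends rightward: [tss - downstream, tss + upstream).
    Windows are clipped at position 0.
    """
    if upstream < 0 or downstream < 0:
        raise ConfigError("window extents must be >= 0")
    if not strand_aware or strand == "+":
        lo, hi = tss - upstream, tss + downstream
    else:
        lo, hi = tss - downstream, tss + upstream
    if lo < 0:
        log.warning("window clipped at position 0 (tss=%d)", tss)
        lo = 0
    return lo, hi


def assign_peaks_to_genes(
    peaks: pd.DataFrame,
    gene_models: pd.DataFrame,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    strand_aware: bool = True,
) -> pd.DataFrame:
    """Peak-to-gene assignment by >= 1 bp overlap with the TSS window.

    Returns a long table (gene_id, chrom, peak_start, peak_end); a peak
    may be assigned to several genes.
    """
    rows = []
    for _, g in gene_models.iterrows():
        lo, hi = gene_window(int(g["tss"]), g["strand"], upstream, downstream,
                             strand_aware)
        sub = peaks[
            (peaks["chrom"] == g["chrom"])
            & (peaks["start"] < hi)
            & (peaks["end"] > lo)
        ]
        for _, peak in sub.iterrows():
            rows.append(
                {
                    "gene_id": g["gene_id"],
                    "chrom": g["chrom"],
                    "peak_start": int(peak["start"]),
                    "peak_end": int(peak["end"]),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "peak_start", "peak_end"])


# ---------------------------------------------------------------------------
# final triage


@dataclass
class TriageReport:
    flags: pd.DataFrame  # per-gene boolean trail
    final_targets: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "final_targets": self.final_targets,
            "flags": {
                g: {k: bool(v) for k, v in row.items()}
                for g, row in self.flags.iterrows()
            },
        }


def triage_targets(
    co_up_genes: set[str],
    tumor_up_genes: set[str],
    common_peak_assignment: Mapping[str, Sequence] | pd.DataFrame,
    gene_effects: pd.DataFrame,
    effect_threshold: float = DEFAULT_EFFECT_THRESHOLD,
    required_lines: Sequence[str] = (),
) -> TriageReport:
    """Nominate genes passing all four evidence filters.

    A gene is a final target iff it is (1) co-upregulated by both
    factors, (2) tumor-upregulated, (3) has >= 1 common binding site
    assigned to its TSS window, and (4) has a gene-effect score strictly
    below ``effect_threshold`` in EVERY required cell line. Targets are
    ordered by ascending mean gene-effect (strongest dependency first).
    """
    required_lines = list(required_lines)
    if not required_lines:
        raise ConfigError("required_lines must name at least one cell line")
    missing_lines = [ln for ln in required_lines if ln not in gene_effects.columns]
    if missing_lines:
        raise ConfigError(f"gene_effects lacks required lines: {missing_lines}")

    if isinstance(common_peak_assignment, pd.DataFrame):
        genes_with_site = set(common_peak_assignment["gene_id"])
    else:
        genes_with_site = {g for g, pk in common_peak_assignment.items() if len(pk) > 0}

    universe = sorted(
        co_up_genes | tumor_up_genes | genes_with_site | set(gene_effects.index)
    )
    rows = {}
    for g in universe:
        if g in gene_effects.index:
            eff = gene_effects.loc[g, required_lines]
            dependency = bool((eff < effect_threshold).all())
        else:
            log.warning("gene %s missing from gene_effects; dependency flag false", g)
            dependency = False
        rows[g] = {
            "co_upregulated_by_both": g in co_up_genes,
            "tumor_upregulated": g in tumor_up_genes,
            "has_common_binding_site_in_window": g in genes_with_site,
            "dependency_in_both_lines": dependency,
        }
    flags = pd.DataFrame.from_dict(rows, orient="index")
    passed = flags.index[flags.all(axis=1)]
    mean_eff = gene_effects.loc[passed, required_lines].mean(axis=1)
    final = list(mean_eff.sort_values().index)
    return TriageReport(flags=flags, final_targets=final)
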