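"""AP-MS interactor filtering and expression-based prioritization.

The bait-specific filter keeps proteins with at least ``min_bait`` unique
peptides in the bait purification and at most ``max_control`` in the
control purification; candidates are then intersected with genes
upregulated in tumors and ranked by descending fold change.
"""

from __future__ import annotations

import pandas as pd

from ._util import InputError, get_logger
from .expression import select_genes

log = get_logger("interactome")


def aggregate_runs(
    peptide_counts: pd.DataFrame, how: str = "max"
) -> pd.DataFrame:
    """Collapse per-run unique-peptide counts to one bait and one control
    column per protein. Columns are matched by bait*/control* prefix;
    ``how`` is "max" (a peptide identified in any run counts) or "sum"."""
    bait_cols = [c for c in peptide_counts.columns if c.startswith("bait")]
    ctrl_cols = [c for c in peptide_counts.columns if c.startswith("control")]
    if not bait_cols or not ctrl_cols:
        raise InputError("need bait* and control* columns")
    if how not in ("max", "sum"):
        raise InputError(f"unknown aggregation: {how}")
    agg = peptide_counts[bait_cols].max(axis=1) if how == "max" else \
        peptide_counts[bait_cols].sum(axis=1)
    ctl = peptide_counts[ctrl_cols].max(axis=1) if how == "max" else \
        peptide_counts[ctrl_cols].sum(axis=1)
    return pd.DataFrame(
        {"unique_peptides_bait": agg, "unique_peptides_control": ctl}
    )


def filter_interactors(
    evidence: pd.DataFrame, min_bait: int = 2, max_control: int = 0
) -> set[str]:
    """Bait-specific proteins: unique_peptides_bait >= min_bait and
    unique_peptides_control <= max_control."""
    if (evidence[["unique_peptides_bait", "unique_peptides_control"]] < 0).any().any():
        raise InputError("peptide counts must be non-negative")
    mask = (evidence["unique_peptides_bait"] >= min_bait) & (
        evidence["unique_peptides_control"] <= max_control
    )
    return set(evidence.index[mask])


def prioritize_interactors(
    interactors: set[str],
    de_results: pd.DataFrame,
    protein_gene_map: pd.DataFrame,
    lfc_min: float = 1.0,
    fdr_max: float = 0.01,
) -> pd.DataFrame:
    """Keep interactors whose gene is tumor-upregulated (lfc >= lfc_min,
    FDR < fdr_max) and rank by descending lfc. Interactors without a DE
    record are excluded with a warning, never silently kept."""
    mapping = protein_gene_map.set_index("protein_id")["gene_id"]
    rows = []
    selected = select_genes(de_results, lfc_min, fdr_max, direction="up")
    for pid in sorted(interactors):
        gene = mapping.get(pid)
        if gene is None or gene not in de_results.index:
            log.warning("interactor %s has no DE record; excluded", pid)
            continue
        if gene in selected:
            rec = de_results.loc[gene]
            rows.append(
                {"protein_id": pid, "gene_id": gene,
                 "lfc": float(rec["lfc"]), "fdr": float(rec["fdr"])}
            )
    out = pd.DataFrame(rows, columns=["protein_id", "gene_id", "lfc", "fdr"])
    return out.sort_values("lfc", ascending=False).reset_index(drop=True)
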