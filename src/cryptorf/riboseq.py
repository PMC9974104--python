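"""Ribo-seq QC and a simplified translated-ORF caller for lncRNA transcripts.

The caller is a deliberate simplification of full ORF-prediction tools:
translation evidence for an ATG ORF is an exact one-sided binomial test
for excess of P-sites in the ORF's reading frame (frame 0) against the
uniform null of 1/3, with Benjamini-Hochberg correction across all tested
candidates. This preserves the inferential role of 3-nt periodicity —
the signature of active translation — without modelling initiation-site
selection or overlapping ORFs.

Coordinates are 0-based half-open on the transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from ._util import InputError, get_logger
from .expression import bh_adjust

log = get_logger("riboseq")

PSITE_COLS = ["replicate_id", "transcript_id", "position", "count"]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfCandidate:
    """A maximal ATG->stop ORF on a transcript; end includes the stop codon."""

    orf_id: str
    transcript_id: str
    start: int
    end: int
    aa_seq: str

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise InputError(f"ORF span must be a multiple of 3: {self.orf_id}")


@dataclass
class OrfCall:
    candidate: OrfCandidate
    n_psites: int
    frame_fractions: tuple[float, float, float] | None
    p_value: float | None
    q_value: float | None = None

    @property
    def tested(self) -> bool:
        return self.p_value is not None


@dataclass
class QcReport:
    length_histogram: dict[int, int]
    frame_fractions_global: tuple[float, float, float] | None
    metagene_start: np.ndarray | None
    metagene_stop: np.ndarray | None
    replicate_r: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "length_histogram": {str(k): int(v) for k, v in sorted(self.length_histogram.items())},
            "frame_fractions_global": (
                list(self.frame_fractions_global)
                if self.frame_fractions_global is not None else None
            ),
            "metagene_start": (
                self.metagene_start.tolist() if self.metagene_start is not None else None
            ),
            "metagene_stop": (
                self.metagene_stop.tolist() if self.metagene_stop is not None else None
            ),
            "replicate_r": self.replicate_r.to_dict(),
        }


# ---------------------------------------------------------------------------
# P-site assignment


def assign_psites(
    aligned_reads: pd.DataFrame,
    offset: int = 12,
    min_length: int = 25,
    max_length: int = 34,
) -> pd.DataFrame:
    """Collapse aligned reads to a P-site count table.

    ``aligned_reads`` needs columns replicate_id, transcript_id,
    five_prime (0-based 5' position) and length. The P-site is placed at
    ``five_prime + offset``; reads outside [min_length, max_length] or
    yielding a negative position are dropped and counted in the log.
    """
    required = {"replicate_id", "transcript_id", "five_prime", "length"}
    missing = required - set(aligned_reads.columns)
    if missing:
        raise InputError(f"aligned reads missing columns: {sorted(missing)}")
    if aligned_reads.empty:
        return pd.DataFrame(columns=PSITE_COLS)

    keep = aligned_reads["length"].between(min_length, max_length)
    n_len_dropped = int((~keep).sum())
    reads = aligned_reads.loc[keep].copy()
    reads["position"] = reads["five_prime"] + offset
    neg = reads["position"] < 0
    if neg.any():
        log.warning("%d reads produced negative P-site positions and were dropped",
                    int(neg.sum()))
        reads = reads.loc[~neg]
    if n_len_dropped:
        log.info("dropped %d reads outside length range [%d, %d]",
                 n_len_dropped, min_length, max_length)

    table = (
        reads.groupby(["replicate_id", "transcript_id", "position"], sort=True)
        .agg(count=("position", "size"), _lensum=("length", "sum"))
        .reset_index()
    )
    table["mean_length"] = table.pop("_lensum") / table["count"]
    return table[PSITE_COLS + ["mean_length"]]


# ---------------------------------------------------------------------------
# QC metrics


def qc_metrics(
    psites: pd.DataFrame,
    transcriptome,
    window: int = 50,
    read_lengths: Iterable[int] | None = None,
) -> QcReport:
    """Global QC of a P-site table against annotated coding regions.

    Frame fractions and metagene profiles use annotated CDSs of coding
    transcripts; the replicate correlation matrix uses per-gene summed
    counts. ``transcriptome`` is a ``synthetic.Transcriptome`` or any
    object with a compatible ``transcripts`` mapping.
    """
    if psites.empty or psites["replicate_id"].nunique() < 1:
        raise InputError("qc_metrics requires a non-empty P-site table")

    hist: dict[int, int] = {}
    if read_lengths is not None:
        vals, counts = np.unique(np.fromiter(read_lengths, dtype=int), return_counts=True)
        hist = {int(v): int(c) for v, c in zip(vals, counts)}

    models = transcriptome.transcripts
    cds_map = {
        tid: m.cds for tid, m in models.items() if getattr(m, "cds", None) is not None
    }

    frame_counts = np.zeros(3)
    mg_start = np.zeros(2 * window + 1)
    mg_stop = np.zeros(2 * window + 1)
    if not cds_map:
        log.warning("no CDS annotations available: frame/metagene QC omitted")
        frame_fractions = None
        metagene_start = metagene_stop = None
    else:
        coding = psites[psites["transcript_id"].isin(cds_map)]
        n_cds = len(cds_map)
        for tid, sub in coding.groupby("transcript_id"):
            cds_start, cds_end = cds_map[tid]
            pos = sub["position"].to_numpy()
            cnt = sub["count"].to_numpy()
            inside = (pos >= cds_start) & (pos < cds_end)
            frames = (pos[inside] - cds_start) % 3
            np.add.at(frame_counts, frames, cnt[inside])
            for anchor, acc in ((cds_start, mg_start), (cds_end - 3, mg_stop)):
                off = pos - anchor
                ok = np.abs(off) <= window
                np.add.at(acc, off[ok] + window, cnt[ok])
        total = frame_counts.sum()
        frame_fractions = tuple(frame_counts / total) if total > 0 else None
        metagene_start = mg_start / max(1, n_cds)
        metagene_stop = mg_stop / max(1, n_cds)

    gene_of = {tid: m.gene_id for tid, m in models.items()}
    per_gene = psites.assign(gene_id=psites["transcript_id"].map(gene_of))
    pivot = (
        per_gene.pivot_table(index="gene_id", columns="replicate_id",
                             values="count", aggfunc="sum", fill_value=0)
    )
    if pivot.shape[1] == 1:
        rep_r = pd.DataFrame([[1.0]], index=pivot.columns, columns=pivot.columns)
    else:
        rep_r = pivot.corr(method="pearson")
    return QcReport(
        length_histogram=hist,
        frame_fractions_global=frame_fractions,
        metagene_start=metagene_start,
        metagene_stop=metagene_stop,
        replicate_r=rep_r,
    )


# ---------------------------------------------------------------------------
# ORF enumeration


def enumerate_atg_orfs(
    transcript_seq: str, transcript_id: str = "tx", min_aa: int = 10
) -> list[OrfCandidate]:
    """All maximal ATG->stop ORFs in the three frames of one transcript.

    Within a frame, each stop codon yields at most one ORF, starting at
    the most 5' ATG since the previous in-frame stop (longest isoform).
    ``min_aa`` is the minimum translated length excluding the stop.
    """
    seq = transcript_seq.upper()
    if set(seq) - set("ACGT"):
        raise InputError("sequence must be over {A,C,G,T}")
    out: list[OrfCandidate] = []
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon == "ATG" and start is None:
                start = pos
            elif codon in _STOPS and start is not None:
                end = pos + 3
                aa_len = (end - start) // 3 - 1
                if aa_len >= min_aa:
                    aa = str(Seq(seq[start : end - 3]).translate())
                    out.append(
                        OrfCandidate(
                            orf_id=f"{transcript_id}:{start}-{end}",
                            transcript_id=transcript_id,
                            start=start,
                            end=end,
                            aa_seq=aa,
                        )
                    )
                start = None
    out.sort(key=lambda c: (c.start, c.end))
    return out


# ---------------------------------------------------------------------------
# translation calling


def call_translated_orfs(
    psites: pd.DataFrame,
    candidates: Sequence[OrfCandidate],
    min_psites: int = 10,
    alpha: float = 0.05,
) -> list[OrfCall]:
    """Frame-bias test per ORF candidate with BH correction across tested ones.

    P-sites (pooled over replicates) within [start, end) are binned by
    frame relative to the ORF start; the p-value is the exact one-sided
    binomial tail P(X >= x0 | n, 1/3) on the frame-0 count. Candidates
    with fewer than ``min_psites`` P-sites are reported untested and are
    excluded from the BH pass. Overlapping candidates are each tested
    independently.
    """
    if min_psites < 1:
        raise InputError("min_psites must be >= 1")
    pooled = (
        psites.groupby(["transcript_id", "position"], sort=False)["count"].sum()
        if not psites.empty
        else pd.Series(dtype=int)
    )
    by_tid: dict[str, pd.Series] = {}
    if len(pooled):
        for tid, sub in pooled.groupby(level=0):
            by_tid[tid] = sub.droplevel(0)

    calls: list[OrfCall] = []
    for cand in candidates:
        sub = by_tid.get(cand.transcript_id)
        if sub is None:
            n, x0, fracs = 0, 0, None
        else:
            pos = sub.index.to_numpy()
            cnt = sub.to_numpy()
            inside = (pos >= cand.start) & (pos < cand.end)
            n = int(cnt[inside].sum())
            frames = (pos[inside] - cand.start) % 3
            fc = np.zeros(3)
            np.add.at(fc, frames, cnt[inside])
            x0 = int(fc[0])
            fracs = tuple(fc / n) if n > 0 else None
        if n < min_psites:
            calls.append(OrfCall(cand, n, fracs, None))
        else:
            p = stats.binomtest(x0, n, 1.0 / 3.0, alternative="greater").pvalue
            calls.append(OrfCall(cand, n, fracs, float(p)))

    tested = [c for c in calls if c.tested]
    if tested:
        qs = bh_adjust(np.array([c.p_value for c in tested]))
        for call, q in zip(tested, qs):
            call.q_value = float(q)
    log.info("tested %d/%d ORF candidates (min_psites=%d)",
             len(tested), len(calls), min_psites)
    return calls


def significant_calls(calls: Iterable[OrfCall], q_max: float = 0.05) -> list[OrfCall]:
    return [c for c in calls if c.tested and c.q_value is not None and c.q_value < q_max]


# ---------------------------------------------------------------------------
# deduplication of highly similar ORFs


def aa_identity(a: str, b: str) -> float:
    """Global amino-acid identity: 1 - edit_distance / max(len)."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def deduplicate_orfs(
    calls: Sequence[OrfCall],
    identity_threshold: float = 0.9,
    identity_fn=aa_identity,
) -> list[OrfCall]:
    """Greedy clustering of ORF calls by global amino-acid identity.

    Calls are visited sorted by (n_psites desc, orf_id asc); each joins
    the first existing cluster whose representative is at least
    ``identity_threshold`` identical, otherwise it founds a new cluster.
    Representatives (cluster founders) are returned in founding order.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise InputError("identity_threshold must lie in (0, 1]")
    ordered = sorted(calls, key=lambda c: (-c.n_psites, c.candidate.orf_id))
    reps: list[OrfCall] = []
    for call in ordered:
        for rep in reps:
            if identity_fn(call.candidate.aa_seq, rep.candidate.aa_seq) >= identity_threshold:
                break
        else:
            reps.append(call)
    return reps


def calls_to_frame(calls: Sequence[OrfCall]) -> pd.DataFrame:
    """Flatten OrfCalls to the TSV-ready table."""
    rows = []
    for c in calls:
        rows.append(
            {
                "orf_id": c.candidate.orf_id,
                "transcript_id": c.candidate.transcript_id,
                "start": c.candidate.start,
                "end": c.candidate.end,
                "n_psites": c.n_psites,
                "frame0_fraction": c.frame_fractions[0] if c.frame_fractions else np.nan,
                "p_value": c.p_value if c.p_value is not None else np.nan,
                "q_value": c.q_value if c.q_value is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)
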