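"""Synthetic study generator with planted ground truth.

Emulates the statistical structure of a cryptic-ORF dependency study in
luminal breast cancer so every downstream stage is testable without any
download: 3-nt periodic ribosome P-site signal on planted lncRNA ORFs,
overdispersed sgRNA screen counts with planted depletion, tumor/normal
expression shifts, exponential survival with expression-linked hazard,
bait-specific AP-MS peptide detection, and co-bound ChIP peak geometry
around transcription start sites, together with DepMap-style gene-effect
scores.

All genes live on one fictional chromosome, spaced far enough apart that
regulatory windows never overlap; transcripts are modelled as two genomic
exons whose concatenation is the transcript sequence. Every generator is
a pure function of its ``FixtureConfig`` — identical config and seed give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._util import ConfigError, get_logger, gtf_attributes, write_bed6, write_fasta, write_gtf

log = get_logger("synthetic")

_STOPS = ("TAA", "TAG", "TGA")
_BASES = np.array(list("ACGT"))

# chromosome layout: genes every GENE_SPACING bp so that the widest
# regulatory window (-30 kb/+10 kb) of one gene never reaches another
GENE_SPACING = 100_000
GENE_OFFSET = 40_000
INTRON_LEN = 2_000


@dataclass
class FixtureConfig:
    """All knobs of the synthetic study, in one place.

    Counts are numbers of items; fractions lie in [0, 1]; ``depletion_fold``
    and ``hazard_ratio`` are multiplicative ratios; ``planted_lfc`` is in
    log2 units. ``periodicity`` is the excess probability (beyond the
    uniform 1/3) that a P-site on a planted ORF falls in frame 0.
    """

    seed: int = 0
    # transcriptome
    n_lnc_transcripts: int = 120
    n_coding_transcripts: int = 60
    planted_orf_fraction: float = 0.5
    # ribo-seq
    periodicity: float = 0.8
    rpf_depth: float = 100.0
    background_rpf_depth: float = 30.0
    n_rpf_replicates: int = 3
    nb_dispersion: float = 0.1
    # CRISPR screen
    n_orfs_screened: int = 0  # 0 = screen every ORF passed in
    sgrnas_per_orf: int = 5
    n_neg_controls: int = 1064
    n_pos_controls: int = 636
    depletion_fold: float = 3.0
    essential_orf_fraction: float = 0.2
    screen_depth: float = 500.0
    n_screen_replicates: int = 2
    # tumor/normal cohort
    n_tumor: int = 50
    n_normal: int = 50
    planted_lfc: float = 2.0
    tumor_up_fraction: float = 0.25
    hazard_ratio: float = 2.5
    survival_horizon: float = 120.0
    median_survival: float = 60.0
    # AP-MS
    n_bait_runs: int = 2
    n_control_runs: int = 2
    n_true_interactors: int = 12
    # regulatory
    co_bound_fraction: float = 0.1
    cell_lines: tuple[str, ...] = ("MCF7", "T47D")
    n_background_peaks: int = 40
    n_ko_samples: int = 6
    ko_noise_sd: float = 0.3

    def validate(self) -> None:
        counts = {
            "n_lnc_transcripts": self.n_lnc_transcripts,
            "n_coding_transcripts": self.n_coding_transcripts,
            "n_neg_controls": self.n_neg_controls,
            "n_pos_controls": self.n_pos_controls,
            "n_tumor": self.n_tumor,
            "n_normal": self.n_normal,
            "n_bait_runs": self.n_bait_runs,
            "n_control_runs": self.n_control_runs,
            "sgrnas_per_orf": self.sgrnas_per_orf,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigError(f"{name} must be >= 0, got {value}")
        fractions = {
            "planted_orf_fraction": self.planted_orf_fraction,
            "periodicity": self.periodicity,
            "essential_orf_fraction": self.essential_orf_fraction,
            "tumor_up_fraction": self.tumor_up_fraction,
            "co_bound_fraction": self.co_bound_fraction,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.depletion_fold < 1:
            raise ConfigError(f"depletion_fold must be >= 1, got {self.depletion_fold}")
        if self.n_lnc_transcripts + self.n_coding_transcripts < 1:
            raise ConfigError("at least one transcript must be requested")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["cell_lines"] = list(self.cell_lines)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FixtureConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "cell_lines" in data:
            data["cell_lines"] = tuple(data["cell_lines"])
        return cls(**data)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per fixture."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])


@dataclass
class GroundTruth:
    """Planted truth sets; every id exists in the generated fixtures."""

    translated_orf_ids: set[str] = field(default_factory=set)
    essential_orf_ids: set[str] = field(default_factory=set)
    tumor_up_gene_ids: set[str] = field(default_factory=set)
    true_interactor_ids: set[str] = field(default_factory=set)
    co_bound_target_ids: set[str] = field(default_factory=set)
    coreg_up_gene_ids: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        data = {k: sorted(v) for k, v in dataclasses.asdict(self).items()}
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    biotype: str  # "lncRNA" | "protein_coding"
    chrom: str
    strand: str
    genome_start: int
    genome_end: int
    seq: str
    cds: tuple[int, int] | None = None  # transcript coords, half-open
    exons: tuple[tuple[int, int], ...] = ()  # genomic coords, half-open

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def tss(self) -> int:
        return self.genome_start if self.strand == "+" else self.genome_end - 1

    @property
    def tts(self) -> int:
        return self.genome_end - 1 if self.strand == "+" else self.genome_start


@dataclass
class PlantedOrf:
    orf_id: str
    transcript_id: str
    start: int  # 0-based, transcript coords
    end: int  # exclusive, multiple-of-3 span incl. stop codon


@dataclass
class Transcriptome:
    transcripts: dict[str, TranscriptModel]
    planted_orfs: list[PlantedOrf]
    chrom: str
    chrom_length: int

    @property
    def lnc_ids(self) -> list[str]:
        return [t for t, m in self.transcripts.items() if m.biotype == "lncRNA"]

    @property
    def coding_ids(self) -> list[str]:
        return [t for t, m in self.transcripts.items() if m.biotype == "protein_coding"]

    def gene_of(self, transcript_id: str) -> str:
        return self.transcripts[transcript_id].gene_id

    def gene_models(self, biotype: str | None = None) -> pd.DataFrame:
        """Gene-level anchor table (gene_id, chrom, strand, tss, tts, exons)."""
        rows = []
        for m in self.transcripts.values():
            if biotype is not None and m.biotype != biotype:
                continue
            rows.append(
                {
                    "gene_id": m.gene_id,
                    "chrom": m.chrom,
                    "strand": m.strand,
                    "tss": m.tss,
                    "tts": m.tts,
                    "start": m.genome_start,
                    "end": m.genome_end,
                    "exons": m.exons,
                }
            )
        return pd.DataFrame(rows)


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _random_orf(rng: np.random.Generator, n_aa: int) -> str:
    """ATG + n_aa sense codons (no in-frame stop) + one stop codon."""
    codons = ["ATG"]
    while len(codons) < n_aa + 1:
        c = "".join(_BASES[rng.integers(0, 4, size=3)])
        if c not in _STOPS:
            codons.append(c)
    codons.append(_STOPS[rng.integers(0, 3)])
    return "".join(codons)


# ---------------------------------------------------------------------------
# transcriptome


def gen_transcriptome(config: FixtureConfig) -> Transcriptome:
    """Build the fictional chromosome, transcript sequences and planted ORFs.

    Planted lncRNA ORFs are preceded by an in-frame stop codon so that the
    most-5' ATG of the planted (frame, stop) pair is the planted start —
    ORF enumeration then recovers planted coordinates exactly.
    """
    config.validate()
    rng = config.rng(1)
    n_total = config.n_lnc_transcripts + config.n_coding_transcripts
    chrom = "chrS"

    n_planted = int(round(config.planted_orf_fraction * config.n_lnc_transcripts))
    planted_idx = set(
        rng.choice(config.n_lnc_transcripts, size=n_planted, replace=False).tolist()
    )

    transcripts: dict[str, TranscriptModel] = {}
    planted: list[PlantedOrf] = []
    order = rng.permutation(n_total)  # interleave biotypes along the chromosome

    for slot, idx in enumerate(order):
        is_lnc = idx < config.n_lnc_transcripts
        if is_lnc:
            tid = f"LNC{idx:04d}"
            gid = f"GLNC{idx:04d}"
            length = int(rng.integers(400, 800))
        else:
            j = idx - config.n_lnc_transcripts
            tid = f"PC{j:04d}"
            gid = f"GPC{j:04d}"
            length = int(rng.integers(600, 1200))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = _random_seq(rng, length)

        cds = None
        if is_lnc and idx in planted_idx:
            n_aa = int(rng.integers(20, 81))
            orf = _random_orf(rng, n_aa)
            start = int(rng.integers(3, length - len(orf)))
            seq[start - 3 : start] = list("TAA")  # in-frame roadblock upstream
            seq[start : start + len(orf)] = list(orf)
            # id convention matches the ORF caller's, so planted ids line up
            # with called/screened ids across the whole study
            planted.append(
                PlantedOrf(
                    orf_id=f"{tid}:{start}-{start + len(orf)}",
                    transcript_id=tid,
                    start=start,
                    end=start + len(orf),
                )
            )
        elif not is_lnc:
            n_aa = int(rng.integers(100, min(201, (length - 60) // 3 - 2)))
            orf = _random_orf(rng, n_aa)
            start = int(rng.integers(30, length - len(orf) - 29))
            seq[start : start + len(orf)] = list(orf)
            cds = (start, start + len(orf))

        genome_start = GENE_OFFSET + slot * GENE_SPACING
        exon1 = length // 2
        exons = (
            (genome_start, genome_start + exon1),
            (genome_start + exon1 + INTRON_LEN, genome_start + length + INTRON_LEN),
        )
        transcripts[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            biotype="lncRNA" if is_lnc else "protein_coding",
            chrom=chrom,
            strand=strand,
            genome_start=genome_start,
            genome_end=genome_start + length + INTRON_LEN,
            seq="".join(seq),
            cds=cds,
            exons=exons,
        )

    chrom_length = GENE_OFFSET * 2 + n_total * GENE_SPACING
    return Transcriptome(
        transcripts=transcripts, planted_orfs=planted, chrom=chrom, chrom_length=chrom_length
    )


# ---------------------------------------------------------------------------
# ribo-seq P-sites


def _draw_positions_in_orf(
    rng: np.random.Generator, n: int, start: int, end: int, periodicity: float
) -> np.ndarray:
    """P-site positions inside [start, end-3): frame 0 w.p. periodicity+(1-periodicity)/3."""
    n_codons = (end - start) // 3 - 1  # exclude the stop codon
    p0 = periodicity + (1.0 - periodicity) / 3.0
    p_rest = (1.0 - periodicity) / 3.0
    frames = rng.choice(3, size=n, p=[p0, p_rest, p_rest])
    codons = rng.integers(0, max(1, n_codons), size=n)
    return start + 3 * codons + frames


def gen_rpf(config: FixtureConfig, transcriptome: Transcriptome) -> pd.DataFrame:
    """Per-replicate P-site count table.

    Planted lncRNA ORFs and annotated CDSs receive 3-nt periodic signal at
    ``rpf_depth`` mean coverage; other lncRNAs receive frame-uniform
    background. Per-transcript rates are Gamma-distributed (negative
    binomial marginal counts) and shared across replicates; replicate
    counts are then independent Poisson draws. Coding transcripts carry an
    initiation spike at the CDS start and no P-sites on the stop codon, so
    metagene profiles show the expected start enrichment / stop depletion.
    """
    if config.rpf_depth <= 0:
        log.warning("rpf_depth is 0 with planted ORFs: returning empty P-site table")
        return pd.DataFrame(columns=["replicate_id", "transcript_id", "position", "count"])

    rng = config.rng(2)
    disp = config.nb_dispersion
    planted_by_tid = {o.transcript_id: o for o in transcriptome.planted_orfs}

    def rate(mean: float) -> float:
        if disp <= 0:
            return mean
        return float(rng.gamma(1.0 / disp, mean * disp))

    rows: list[tuple[str, str, int]] = []
    for tid, model in transcriptome.transcripts.items():
        if model.biotype == "lncRNA":
            if tid in planted_by_tid:
                orf = planted_by_tid[tid]
                lam = rate(config.rpf_depth)
                for rep in range(config.n_rpf_replicates):
                    n = int(rng.poisson(lam))
                    pos = _draw_positions_in_orf(
                        rng, n, orf.start, orf.end, config.periodicity
                    )
                    rows.extend((f"rep{rep + 1}", tid, int(p)) for p in pos)
            else:
                lam = rate(config.background_rpf_depth)
                for rep in range(config.n_rpf_replicates):
                    n = int(rng.poisson(lam))
                    pos = rng.integers(0, model.length, size=n)
                    rows.extend((f"rep{rep + 1}", tid, int(p)) for p in pos)
        else:
            cds_start, cds_end = model.cds  # type: ignore[misc]
            lam = rate(config.rpf_depth)
            for rep in range(config.n_rpf_replicates):
                n = int(rng.poisson(lam))
                n_init = int(round(0.08 * n))  # initiation spike at the start codon
                pos = _draw_positions_in_orf(
                    rng, n - n_init, cds_start, cds_end, config.periodicity
                )
                rows.extend((f"rep{rep + 1}", tid, int(p)) for p in pos)
                rows.extend((f"rep{rep + 1}", tid, cds_start) for _ in range(n_init))

    df = pd.DataFrame(rows, columns=["replicate_id", "transcript_id", "position"])
    df = (
        df.groupby(["replicate_id", "transcript_id", "position"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return df


def psites_to_reads(
    psites: pd.DataFrame, config: FixtureConfig, offset: int = 12
) -> pd.DataFrame:
    """Expand a P-site table into per-read rows with 5' positions and lengths.

    The inverse of P-site assignment: 5' end = position - offset, lengths
    drawn around the canonical ~30 nt ribosome footprint. Used to exercise
    the read-level entry point of the QC stage.
    """
    rng = config.rng(7)
    expanded = psites.loc[psites.index.repeat(psites["count"])]
    n = len(expanded)
    lengths = np.clip(np.round(rng.normal(30.0, 1.5, size=n)).astype(int), 26, 34)
    return pd.DataFrame(
        {
            "replicate_id": expanded["replicate_id"].to_numpy(),
            "transcript_id": expanded["transcript_id"].to_numpy(),
            "five_prime": expanded["position"].to_numpy() - offset,
            "length": lengths,
        }
    )


# ---------------------------------------------------------------------------
# CRISPR screen


def gen_screen(
    config: FixtureConfig,
    orf_ids: Sequence[str],
    essential_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, set[str]]:
    """sgRNA library, raw day0/day21 count matrix, and the planted essential set.

    Each guide has a Gamma day-0 abundance rate shared across replicates;
    day-21 rates of guides targeting essential ORFs and of positive
    controls are divided by ``depletion_fold``. Counts are Poisson draws
    around the guide rate (negative-binomial marginally).
    """
    if config.depletion_fold < 1:
        raise ConfigError(f"depletion_fold must be >= 1, got {config.depletion_fold}")
    if config.sgrnas_per_orf < 1:
        raise ConfigError("sgrnas_per_orf must be >= 1")
    rng = config.rng(3)
    orf_ids = list(orf_ids)
    if config.n_orfs_screened and config.n_orfs_screened < len(orf_ids):
        orf_ids = orf_ids[: config.n_orfs_screened]

    if essential_ids is None:
        n_ess = int(round(config.essential_orf_fraction * len(orf_ids)))
        essential = set(rng.choice(len(orf_ids), size=n_ess, replace=False).tolist())
        essential_ids_set = {orf_ids[i] for i in essential}
    else:
        essential_ids_set = set(essential_ids)

    lib_rows = []
    for orf in orf_ids:
        for k in range(config.sgrnas_per_orf):
            lib_rows.append((f"sg_{orf}_{k + 1}", orf, "targeting"))
    for k in range(config.n_pos_controls):
        lib_rows.append((f"sg_pos_{k + 1}", None, "positive_control"))
    for k in range(config.n_neg_controls):
        lib_rows.append((f"sg_neg_{k + 1}", None, "negative_control"))
    library = pd.DataFrame(lib_rows, columns=["sgrna_id", "target_orf_id", "class"])

    depleted = library["class"].eq("positive_control").to_numpy() | (
        library["target_orf_id"].isin(essential_ids_set).to_numpy()
    )
    n_guides = len(library)
    disp = config.nb_dispersion
    if disp > 0:
        rate0 = rng.gamma(1.0 / disp, config.screen_depth * disp, size=n_guides)
    else:
        rate0 = np.full(n_guides, config.screen_depth)
    rate21 = np.where(depleted, rate0 / config.depletion_fold, rate0)

    counts = {"sgrna_id": library["sgrna_id"]}
    for rep in range(1, config.n_screen_replicates + 1):
        counts[f"day0_r{rep}"] = rng.poisson(rate0)
    for rep in range(1, config.n_screen_replicates + 1):
        counts[f"day21_r{rep}"] = rng.poisson(rate21)
    count_df = pd.DataFrame(counts).set_index("sgrna_id")
    return library, count_df, essential_ids_set


# ---------------------------------------------------------------------------
# tumor/normal cohort with survival


def gen_cohort(
    config: FixtureConfig,
    gene_ids: Sequence[str],
    force_up_ids: Sequence[str] = (),
    survival_gene: str | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, set[str]]:
    """Expression matrix (log2 scale), group labels, survival table, up-gene set.

    Expression is Gaussian on the log2 scale around a gene baseline;
    planted tumor-up genes are shifted by ``planted_lfc`` in tumors.
    Survival times for tumor samples are exponential; the hazard of the
    above-median stratum of the designated gene is multiplied by
    ``hazard_ratio``, with administrative censoring at the horizon.
    """
    if config.n_tumor < 2 or config.n_normal < 2:
        raise ConfigError("n_tumor and n_normal must both be >= 2")
    rng = config.rng(4)
    gene_ids = list(gene_ids)
    n_up = int(round(config.tumor_up_fraction * len(gene_ids)))
    pool = [g for g in gene_ids if g not in set(force_up_ids)]
    n_extra = max(0, n_up - len(force_up_ids))
    extra = rng.choice(len(pool), size=min(n_extra, len(pool)), replace=False)
    up_ids = set(force_up_ids) | {pool[i] for i in extra}

    tumor_cols = [f"T{i + 1:03d}" for i in range(config.n_tumor)]
    normal_cols = [f"N{i + 1:03d}" for i in range(config.n_normal)]
    baseline = rng.normal(5.0, 1.5, size=len(gene_ids))
    mat = rng.normal(0.0, 1.0, size=(len(gene_ids), config.n_tumor + config.n_normal))
    mat += baseline[:, None]
    up_mask = np.array([g in up_ids for g in gene_ids])
    mat[np.ix_(up_mask, np.arange(config.n_tumor))] += config.planted_lfc

    expr = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"),
                        columns=tumor_cols + normal_cols)
    labels = pd.Series(
        ["tumor"] * config.n_tumor + ["normal"] * config.n_normal,
        index=expr.columns,
        name="group",
    )

    if survival_gene is None:
        survival_gene = sorted(up_ids)[0] if up_ids else gene_ids[0]
    tumor_expr = expr.loc[survival_gene, tumor_cols]
    high = (tumor_expr >= tumor_expr.median()).to_numpy()
    base_hazard = np.log(2.0) / config.median_survival
    hazard = base_hazard * np.where(high, config.hazard_ratio, 1.0)
    times = rng.exponential(1.0 / hazard)
    event = (times <= config.survival_horizon).astype(int)
    times = np.minimum(times, config.survival_horizon)
    survival = pd.DataFrame(
        {
            "sample_id": tumor_cols,
            "time": np.round(times, 4),
            "event": event,
            "stratum": np.where(high, "high", "low"),
        }
    )
    return expr, labels, survival, up_ids


# ---------------------------------------------------------------------------
# AP-MS


def gen_apms(
    config: FixtureConfig,
    protein_ids: Sequence[str],
    true_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, set[str]]:
    """Unique-peptide counts per protein for bait and control runs.

    True interactors get >=2 unique peptides in every bait run and zero in
    all control runs; background proteins get overlapping peptide counts
    in both, with at least one control peptide so the bait-specific filter
    separates the classes by construction.
    """
    if config.n_bait_runs < 1 or config.n_control_runs < 1:
        raise ConfigError("n_bait_runs and n_control_runs must be >= 1")
    rng = config.rng(5)
    protein_ids = list(protein_ids)
    if true_ids is None:
        n_true = min(config.n_true_interactors, len(protein_ids))
        chosen = rng.choice(len(protein_ids), size=n_true, replace=False)
        true_set = {protein_ids[i] for i in chosen}
    else:
        true_set = set(true_ids)

    rows = []
    for pid in protein_ids:
        is_true = pid in true_set
        row: dict[str, object] = {"protein_id": pid}
        for r in range(1, config.n_bait_runs + 1):
            row[f"bait_r{r}"] = int(2 + rng.poisson(3)) if is_true else int(rng.poisson(2))
        for r in range(1, config.n_control_runs + 1):
            row[f"control_r{r}"] = 0 if is_true else int(1 + rng.poisson(1))
        rows.append(row)
    return pd.DataFrame(rows).set_index("protein_id"), true_set


# ---------------------------------------------------------------------------
# knockout/knockdown expression contrasts (consumed by the co-regulation flag)


def gen_ko_expression(
    config: FixtureConfig,
    gene_ids: Sequence[str],
    down_upon_ko_ids: Sequence[str],
    stream: int,
) -> tuple[pd.DataFrame, pd.Series]:
    """Expression matrix for one knockout-vs-control contrast.

    Genes in ``down_upon_ko_ids`` (i.e. genes upregulated by the factor)
    are shifted down by ``planted_lfc`` in the knockout samples. Residual
    noise uses ``ko_noise_sd``: cell-line replicates vary far less than
    tumor-cohort samples.
    """
    rng = config.rng(stream)
    gene_ids = list(gene_ids)
    n = config.n_ko_samples
    ko_cols = [f"KO{i + 1:02d}" for i in range(n)]
    ctrl_cols = [f"CTRL{i + 1:02d}" for i in range(n)]
    baseline = rng.normal(5.0, 1.5, size=len(gene_ids))
    mat = rng.normal(0.0, config.ko_noise_sd, size=(len(gene_ids), 2 * n)) + baseline[:, None]
    down = np.array([g in set(down_upon_ko_ids) for g in gene_ids])
    mat[np.ix_(down, np.arange(n))] -= config.planted_lfc
    expr = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"),
                        columns=ko_cols + ctrl_cols)
    labels = pd.Series(["ko"] * n + ["control"] * n, index=expr.columns, name="group")
    return expr, labels


# ---------------------------------------------------------------------------
# regulatory fixture: peaks, gene effects, planted targets and decoys


@dataclass
class RegulatoryFixture:
    peaks_a: pd.DataFrame  # BED6-style frames
    peaks_b: pd.DataFrame
    gene_effects: pd.DataFrame  # gene x cell line
    co_bound_target_ids: set[str]
    decoys: dict[str, str]  # gene_id -> failure mode label
    ko_down_a: set[str]  # genes down upon factor-A knockout
    ko_down_b: set[str]


def _window(tss: int, strand: str, upstream: int = 30_000, downstream: int = 10_000):
    if strand == "+":
        return max(0, tss - upstream), tss + downstream
    return max(0, tss - downstream), tss + upstream


def gen_regulatory(
    config: FixtureConfig,
    gene_models: pd.DataFrame,
    target_ids: Sequence[str] | None = None,
) -> RegulatoryFixture:
    """Two ChIP peak sets, a gene-effect table, and planted target structure.

    Planted co-bound targets receive one peak from each factor at a shared
    locus inside their -30 kb/+10 kb strand-aware TSS window and
    gene-effect scores below -0.2 in both cell lines. Decoy genes each
    break exactly one link of the triage chain (dependency, common
    binding, window placement, tumor-upregulation, or co-regulation).
    Background peaks are factor-specific and placed outside every gene
    window, so the common peak set contains only planted co-bound loci.
    """
    rng = config.rng(6)
    gm = gene_models.set_index("gene_id")
    genes = list(gm.index)

    if target_ids is None:
        n_targets = max(1, int(round(config.co_bound_fraction * len(genes))))
        chosen = rng.choice(len(genes), size=min(n_targets + 5, len(genes)), replace=False)
        picked = [genes[i] for i in chosen]
        targets = picked[:n_targets]
        decoy_pool = picked[n_targets:]
    else:
        targets = list(target_ids)
        decoy_pool = [g for g in genes if g not in set(targets)]
        idx = rng.choice(len(decoy_pool), size=min(5, len(decoy_pool)), replace=False)
        decoy_pool = [decoy_pool[i] for i in idx]

    decoy_modes = ["weak_dependency", "single_factor", "outside_window",
                   "not_tumor_up", "not_coregulated"]
    decoys = {g: m for g, m in zip(decoy_pool, decoy_modes)}

    peaks_a: list[dict] = []
    peaks_b: list[dict] = []

    def add_cobound_peak(gene: str, inside: bool) -> None:
        row = gm.loc[gene]
        lo, hi = _window(int(row["tss"]), row["strand"])
        if inside:
            x = int(rng.integers(lo + 1_000, hi - 2_000))
        else:  # just beyond the window on the downstream side
            x = hi + int(rng.integers(5_000, 15_000))
        peaks_a.append({"chrom": row["chrom"], "start": x, "end": x + 400,
                        "name": f"A_{gene}", "score": 100, "strand": "."})
        peaks_b.append({"chrom": row["chrom"], "start": x + 100, "end": x + 500,
                        "name": f"B_{gene}", "score": 100, "strand": "."})

    for gene in targets:
        add_cobound_peak(gene, inside=True)
    for gene, mode in decoys.items():
        row = gm.loc[gene]
        if mode == "single_factor":
            lo, hi = _window(int(row["tss"]), row["strand"])
            x = int(rng.integers(lo + 1_000, hi - 2_000))
            peaks_a.append({"chrom": row["chrom"], "start": x, "end": x + 400,
                            "name": f"A_{gene}", "score": 100, "strand": "."})
        elif mode == "outside_window":
            add_cobound_peak(gene, inside=False)
        else:  # co-bound in window; the gene fails triage elsewhere
            add_cobound_peak(gene, inside=True)

    # factor-specific background peaks, kept clear of every gene window
    windows = [
        _window(int(r["tss"]), r["strand"]) for _, r in gene_models.iterrows()
    ]

    def far_from_windows(x: int, pad: int = 1_000) -> bool:
        return all(x + 400 + pad <= lo or x >= hi + pad for lo, hi in windows)

    chrom = gene_models["chrom"].iloc[0]
    chrom_len = int(gene_models["end"].max()) + GENE_OFFSET
    for which, peaks in (("A", peaks_a), ("B", peaks_b)):
        placed = 0
        while placed < config.n_background_peaks:
            x = int(rng.integers(0, chrom_len - 400))
            if far_from_windows(x):
                peaks.append({"chrom": chrom, "start": x, "end": x + 400,
                              "name": f"{which}_bg_{placed + 1}", "score": 50,
                              "strand": "."})
                placed += 1

    peaks_a_df = pd.DataFrame(peaks_a).sort_values(["chrom", "start"]).reset_index(drop=True)
    peaks_b_df = pd.DataFrame(peaks_b).sort_values(["chrom", "start"]).reset_index(drop=True)

    # gene-effect scores: dependency planted for targets and the decoys
    # that must fail elsewhere; "weak_dependency" stays above -0.2
    effects = pd.DataFrame(
        np.clip(rng.normal(0.0, 0.1, size=(len(genes), len(config.cell_lines))),
                -0.19, None),
        index=pd.Index(genes, name="gene_id"),
        columns=list(config.cell_lines),
    )
    dependent = set(targets) | {g for g, m in decoys.items() if m != "weak_dependency"}
    for g in dependent:
        effects.loc[g] = np.round(rng.uniform(-1.0, -0.3, size=len(config.cell_lines)), 4)
    for g, m in decoys.items():
        if m == "weak_dependency":
            effects.loc[g] = np.round(rng.uniform(-0.15, 0.1, size=len(config.cell_lines)), 4)
    effects = effects.round(4)

    coreg = set(targets) | {g for g, m in decoys.items() if m != "not_coregulated"}
    only_a = {g for g, m in decoys.items() if m == "not_coregulated"}
    return RegulatoryFixture(
        peaks_a=peaks_a_df,
        peaks_b=peaks_b_df,
        gene_effects=effects,
        co_bound_target_ids=set(targets),
        decoys=decoys,
        ko_down_a=coreg | only_a,
        ko_down_b=set(coreg),
    )


# ---------------------------------------------------------------------------
# whole-study orchestration


@dataclass
class StudyFixture:
    config: FixtureConfig
    transcriptome: Transcriptome
    psites: pd.DataFrame
    screen_library: pd.DataFrame
    screen_counts: pd.DataFrame
    expression: pd.DataFrame
    group_labels: pd.Series
    survival: pd.DataFrame
    apms: pd.DataFrame
    protein_gene_map: pd.DataFrame
    ko_expr_a: pd.DataFrame
    ko_labels_a: pd.Series
    ko_expr_b: pd.DataFrame
    ko_labels_b: pd.Series
    regulatory: RegulatoryFixture
    truth: GroundTruth
    survival_gene: str = ""


def generate_study(config: FixtureConfig) -> StudyFixture:
    """Generate every input of the end-to-end pipeline with coherent truth.

    The planted driver genes are simultaneously co-regulated by both
    factors, tumor-upregulated, co-bound within their TSS window, and
    dependencies in both cell lines, so the final triage should nominate
    exactly these genes. Host genes of essential lncRNA ORFs are forced
    tumor-up so the screen-to-expression funnel stays populated.
    """
    config.validate()
    rng = config.rng(0)
    transcriptome = gen_transcriptome(config)
    psites = gen_rpf(config, transcriptome)

    orf_ids = sorted(o.orf_id for o in transcriptome.planted_orfs)
    library, counts, essential = gen_screen(config, orf_ids)

    coding_genes = sorted(
        transcriptome.transcripts[t].gene_id for t in transcriptome.coding_ids
    )
    gene_models = transcriptome.gene_models(biotype="protein_coding")
    n_targets = max(1, int(round(config.co_bound_fraction * len(coding_genes))))
    chosen = rng.choice(len(coding_genes), size=min(n_targets, len(coding_genes)),
                        replace=False)
    target_ids = sorted(coding_genes[i] for i in chosen)
    reg = gen_regulatory(config, gene_models, target_ids=target_ids)

    # cohort over both lncRNA and coding genes; drivers and most essential-ORF
    # host genes forced into the tumor-up set
    lnc_genes = sorted(
        transcriptome.transcripts[t].gene_id for t in transcriptome.lnc_ids
    )
    orf_host_gene = {
        o.orf_id: transcriptome.gene_of(o.transcript_id) for o in transcriptome.planted_orfs
    }
    ess_hosts = sorted({orf_host_gene[o] for o in sorted(essential)})
    forced_up = sorted(
        set(target_ids)
        | set(ess_hosts[: max(1, len(ess_hosts) * 3 // 4)])
        | {g for g, m in reg.decoys.items() if m != "not_tumor_up"}
    )
    all_genes = lnc_genes + coding_genes
    designated_survival_gene = ess_hosts[0] if ess_hosts else None
    expr, labels, survival, tumor_up = gen_cohort(
        config, all_genes, force_up_ids=forced_up,
        survival_gene=designated_survival_gene,
    )
    if designated_survival_gene is None:
        designated_survival_gene = sorted(tumor_up)[0] if tumor_up else all_genes[0]

    protein_ids = [f"PROT_{g}" for g in coding_genes]
    mapping = pd.DataFrame({"protein_id": protein_ids, "gene_id": coding_genes})
    up_coding = [g for g in coding_genes if g in tumor_up]
    other_coding = [g for g in coding_genes if g not in tumor_up]
    n_true = min(config.n_true_interactors, len(coding_genes))
    n_from_up = min(n_true // 2 + 1, len(up_coding))
    pick_up = rng.choice(len(up_coding), size=n_from_up, replace=False) if up_coding else []
    rest = n_true - n_from_up
    pick_other = (
        rng.choice(len(other_coding), size=min(rest, len(other_coding)), replace=False)
        if other_coding else []
    )
    true_proteins = sorted(
        {f"PROT_{up_coding[i]}" for i in pick_up}
        | {f"PROT_{other_coding[i]}" for i in pick_other}
    )
    apms, true_set = gen_apms(config, protein_ids, true_ids=true_proteins)

    ko_a, lab_a = gen_ko_expression(config, coding_genes, sorted(reg.ko_down_a), stream=8)
    ko_b, lab_b = gen_ko_expression(config, coding_genes, sorted(reg.ko_down_b), stream=9)

    truth = GroundTruth(
        translated_orf_ids=set(orf_ids),
        essential_orf_ids=set(essential),
        tumor_up_gene_ids=set(tumor_up),
        true_interactor_ids=set(true_set),
        co_bound_target_ids=set(reg.co_bound_target_ids),
        coreg_up_gene_ids=set(reg.ko_down_a & reg.ko_down_b),
    )
    return StudyFixture(
        config=config,
        transcriptome=transcriptome,
        psites=psites,
        screen_library=library,
        screen_counts=counts,
        expression=expr,
        group_labels=labels,
        survival=survival,
        apms=apms,
        protein_gene_map=mapping,
        ko_expr_a=ko_a,
        ko_labels_a=lab_a,
        ko_expr_b=ko_b,
        ko_labels_b=lab_b,
        regulatory=reg,
        truth=truth,
        survival_gene=designated_survival_gene,
    )


# ---------------------------------------------------------------------------
# on-disk serialization (FASTA/GTF/BED/TSV/JSON/YAML)


def write_study(study: StudyFixture, outdir: str | Path) -> dict[str, Path]:
    """Materialize every fixture as plain-text files; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def p(name: str) -> Path:
        paths[name.split(".")[0]] = outdir / name
        return outdir / name

    study.config.to_yaml(p("config.yaml"))
    tr = study.transcriptome
    write_fasta(
        p("transcripts.fa"),
        ((tid, m.seq) for tid, m in sorted(tr.transcripts.items())),
    )
    gtf_rows = []
    for tid, m in sorted(tr.transcripts.items()):
        attrs = dict(gene_id=m.gene_id, transcript_id=tid, gene_biotype=m.biotype)
        gtf_rows.append(
            dict(seqname=m.chrom, feature="transcript", start=m.genome_start,
                 end=m.genome_end, strand=m.strand, attribute=gtf_attributes(**attrs))
        )
        for ex_start, ex_end in m.exons:
            gtf_rows.append(
                dict(seqname=m.chrom, feature="exon", start=ex_start, end=ex_end,
                     strand=m.strand, attribute=gtf_attributes(**attrs))
            )
    write_gtf(p("models.gtf"), gtf_rows)
    orf_df = pd.DataFrame(
        [dataclasses.asdict(o) for o in tr.planted_orfs]
    ).sort_values("orf_id")
    orf_df.to_csv(p("planted_orfs.tsv"), sep="\t", index=False)

    study.psites.to_csv(p("psites.tsv"), sep="\t", index=False)
    study.screen_library.to_csv(p("screen_library.tsv"), sep="\t", index=False)
    study.screen_counts.to_csv(p("screen_counts.tsv"), sep="\t")
    study.expression.round(4).to_csv(p("expression.tsv"), sep="\t")
    study.group_labels.to_frame().to_csv(p("group_labels.tsv"), sep="\t")
    study.survival.to_csv(p("survival.tsv"), sep="\t", index=False)
    study.apms.to_csv(p("apms_peptides.tsv"), sep="\t")
    study.protein_gene_map.to_csv(p("protein_gene_map.tsv"), sep="\t", index=False)
    study.ko_expr_a.round(4).to_csv(p("ko_factor_a.tsv"), sep="\t")
    study.ko_labels_a.to_frame().to_csv(p("ko_factor_a_labels.tsv"), sep="\t")
    study.ko_expr_b.round(4).to_csv(p("ko_factor_b.tsv"), sep="\t")
    study.ko_labels_b.to_frame().to_csv(p("ko_factor_b_labels.tsv"), sep="\t")
    write_bed6(p("peaks_factor_a.bed"), study.regulatory.peaks_a)
    write_bed6(p("peaks_factor_b.bed"), study.regulatory.peaks_b)
    study.regulatory.gene_effects.to_csv(p("gene_effects.tsv"), sep="\t")
    study.truth.to_json(p("ground_truth.json"))
    return paths
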