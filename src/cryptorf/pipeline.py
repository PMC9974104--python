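"""End-to-end orchestration of the cryptic-ORF dependency analysis.

Runs ribo-seq QC and ORF calling, the CRISPR screen, tumor/normal
expression and survival, AP-MS prioritization, and the regulatory target
triage, materializing every intermediate table — the filter trail is the
scientific product. Also houses the two closed-form laboratory
utilities (2^-ddCT fold change and the ellipsoid tumor-volume formula)
and the pipeline configuration whose defaults are the printed analysis
thresholds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression, interactome, regulatory, riboseq, screen
from ._util import ConfigError, get_logger, write_bed6
from .synthetic import FixtureConfig, StudyFixture, generate_study, write_study

log = get_logger("pipeline")

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """All stage thresholds; defaults are the standard analysis thresholds of this workflow."""

    fixture: FixtureConfig = field(default_factory=FixtureConfig)
    # ribo-seq / ORF calling
    psite_offset: int = 12
    min_aa: int = 10
    min_psites: int = 10
    orf_alpha: float = 0.05
    orf_q_max: float = 0.05
    dedup_identity: float = 0.9
    # CRISPR screen
    screen_norm_method: str = "control-median"
    screen_lfc_threshold: float = -float(np.log2(1.5))
    screen_p_threshold: float = 0.05
    screen_min_sgrnas: int = 2
    # tumor-vs-normal expression (lncRNA upregulation filter)
    lnc_up_lfc_min: float = float(np.log2(1.2))
    lnc_up_fdr_max: float = 0.01
    # knockout/knockdown differential expression
    ko_de_lfc_min: float = float(np.log2(1.5))
    ko_de_fdr_max: float = 0.05
    # AP-MS expression filter
    apms_min_bait: int = 2
    apms_max_control: int = 0
    apms_lfc_min: float = 1.0
    apms_fdr_max: float = 0.01
    # regulatory window and dependency
    window_upstream: int = 30_000
    window_downstream: int = 10_000
    effect_threshold: float = -0.2

    def validate(self) -> None:
        self.fixture.validate()
        if self.screen_lfc_threshold > 0:
            raise ConfigError("screen_lfc_threshold must be <= 0 (depletion)")
        if self.effect_threshold > 0:
            raise ConfigError("effect_threshold must be <= 0 (dependency)")
        if self.window_upstream < 0 or self.window_downstream < 0:
            raise ConfigError("window extents must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["fixture"]["cell_lines"] = list(self.fixture.cell_lines)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        fx = data.pop("fixture", {})
        if "cell_lines" in fx:
            fx["cell_lines"] = tuple(fx["cell_lines"])
        return cls(fixture=FixtureConfig(**fx), **data)


# ---------------------------------------------------------------------------
# closed-form utilities


def ddct_fold_change(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative qPCR expression by the 2^-ddCT method.

    ddCT = (CT_target - CT_reference) in the treated sample minus the
    same difference in the control sample.
    """
    for v in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not np.isfinite(v):
            raise ConfigError("CT values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))


def tumor_volume(length: float, width: float) -> float:
    """Ellipsoid approximation L * W^2 / 2; warns when W > L."""
    if length < 0 or width < 0:
        raise ConfigError("diameters must be non-negative")
    if width > length:
        log.warning("W (%g) exceeds L (%g); check caliper orientation", width, length)
    return float(length * width * width / 2.0)


# ---------------------------------------------------------------------------
# run report


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


@dataclass
class RunReport:
    seed: int
    version: str
    counts: dict[str, int] = field(default_factory=dict)
    assumptions: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


_ASSUMPTIONS = [
    "ORF translation evidence: exact one-sided binomial frame-bias test, "
    "not a full initiation-site model",
    "sgRNA p-values: +1-corrected empirical tail against negative-control lfcs",
    "differential expression: two-sided Wilcoxon rank-sum on log2 values",
    "AP-MS peptide aggregation across runs: maximum",
    "survival dichotomization: median expression split",
    "common binding sites: coordinate intersection of merged peak sets",
]


# ---------------------------------------------------------------------------
# the end-to-end run


def run_all(
    config: PipelineConfig, outdir: str | Path, write_fixtures: bool = False
) -> tuple[RunReport, dict]:
    """Execute every stage on a synthetic study and write all artifacts.

    Returns the run report and a dict of in-memory stage results. Each
    stage's outputs are written before the next stage begins; identical
    config and seed reproduce every file byte for byte.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    root = logging.getLogger("cryptorf")
    root.addHandler(collector)
    try:
        return _run_all(config, outdir, write_fixtures, collector)
    finally:
        root.removeHandler(collector)


def _run_all(config, outdir: Path, write_fixtures: bool, collector) -> tuple[RunReport, dict]:
    report = RunReport(seed=config.fixture.seed, version=__version__,
                       assumptions=list(_ASSUMPTIONS))
    results: dict = {}

    study: StudyFixture = generate_study(config.fixture)
    if write_fixtures:
        write_study(study, outdir / "fixtures")
    results["study"] = study
    truth = study.truth
    tr = study.transcriptome

    # -- stage 1: ribo-seq QC and translated-ORF calling -------------------
    stage = "riboseq"
    try:
        qc = riboseq.qc_metrics(study.psites, tr)
        with open(outdir / "qc_report.json", "w") as fh:
            json.dump(qc.to_dict(), fh, indent=2, sort_keys=True)
        candidates = []
        for tid in sorted(tr.lnc_ids):
            candidates.extend(
                riboseq.enumerate_atg_orfs(tr.transcripts[tid].seq, tid,
                                           min_aa=config.min_aa)
            )
        calls = riboseq.call_translated_orfs(
            study.psites, candidates, min_psites=config.min_psites,
            alpha=config.orf_alpha,
        )
        called = riboseq.significant_calls(calls, q_max=config.orf_q_max)
        representatives = riboseq.deduplicate_orfs(called, config.dedup_identity)
        riboseq.calls_to_frame(calls).to_csv(outdir / "orf_calls.tsv", sep="\t",
                                             index=False)
        riboseq.calls_to_frame(representatives).to_csv(
            outdir / "orf_representatives.tsv", sep="\t", index=False
        )
    except Exception as exc:  # pragma: no cover - abort path
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
    report.counts.update(
        orf_candidates=len(candidates),
        orf_calls_significant=len(called),
        orf_representatives=len(representatives),
    )
    results.update(qc=qc, calls=calls, called=called, representatives=representatives)
    log.info("filter translated-ORFs: %d candidates -> %d called -> %d representatives",
             len(candidates), len(called), len(representatives))

    # -- stage 2: CRISPR screen --------------------------------------------
    stage = "screen"
    try:
        norm, size_factors = screen.normalize_counts(
            study.screen_counts, study.screen_library, method=config.screen_norm_method
        )
        stats_df = screen.sgrna_stats(norm, study.screen_library)
        hits = screen.call_hits(
            stats_df, study.screen_library,
            lfc_threshold=config.screen_lfc_threshold,
            p_threshold=config.screen_p_threshold,
            min_sgrnas=config.screen_min_sgrnas,
        )
        screen_qc = screen.positive_control_qc(stats_df, study.screen_library)
        stats_df.round(6).to_csv(outdir / "sgrna_stats.tsv", sep="\t")
        hits.to_csv(outdir / "orf_hits.tsv", sep="\t")
        with open(outdir / "screen_qc.json", "w") as fh:
            json.dump(screen_qc.to_dict(), fh, indent=2, sort_keys=True)
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
    hit_ids = set(hits.index[hits["is_hit"]])
    report.counts.update(sgrnas=len(stats_df), orf_hits=len(hit_ids))
    results.update(sgrna_stats=stats_df, hits=hits, screen_qc=screen_qc)
    log.info("filter screen-hits: %d ORFs screened -> %d hits",
             int(hits.shape[0]), len(hit_ids))

    # -- stage 3: tumor/normal expression and survival ---------------------
    stage = "expression"
    try:
        de_cohort = expression.differential_expression(
            study.expression, study.group_labels, groups=("normal", "tumor")
        )
        de_cohort.round(6).to_csv(outdir / "de_cohort.tsv", sep="\t")
        tumor_up = expression.select_genes(
            de_cohort, config.lnc_up_lfc_min, config.lnc_up_fdr_max, "up"
        )
        # ORF-level funnel: representatives -> screen hits -> tumor-up host gene
        rep_ids = {c.candidate.orf_id for c in representatives}
        host = {o.orf_id: tr.gene_of(o.transcript_id) for o in tr.planted_orfs}
        called_hosts = {
            c.candidate.orf_id: tr.gene_of(c.candidate.transcript_id)
            for c in representatives
        }
        host.update(called_hosts)
        candidate_orfs = sorted(
            o for o in (rep_ids & hit_ids) if host.get(o) in tumor_up
        )
        pd.DataFrame({"orf_id": candidate_orfs}).to_csv(
            outdir / "candidate_orfs.tsv", sep="\t", index=False
        )
        tumor_cols = study.group_labels.index[study.group_labels == "tumor"]
        expr_gene = study.survival_gene
        lr = expression.logrank_by_expression(
            study.survival,
            study.expression.loc[expr_gene, tumor_cols],
        )
        with open(outdir / "survival_logrank.json", "w") as fh:
            json.dump(
                {"gene": expr_gene, "statistic": lr.statistic, "p_value": lr.p_value,
                 "n_high": lr.n_high, "n_low": lr.n_low},
                fh, indent=2, sort_keys=True,
            )
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
    report.counts.update(
        tumor_up_genes=len(tumor_up), candidate_orfs=len(candidate_orfs)
    )
    results.update(de_cohort=de_cohort, tumor_up=tumor_up,
                   candidate_orfs=candidate_orfs, logrank=lr)
    log.info("filter tumor-up: %d hits -> %d candidate ORFs",
             len(hit_ids & rep_ids), len(candidate_orfs))

    # -- stage 4: AP-MS interactome ----------------------------------------
    stage = "interactome"
    try:
        evidence = interactome.aggregate_runs(study.apms, how="max")
        interactors = interactome.filter_interactors(
            evidence, min_bait=config.apms_min_bait, max_control=config.apms_max_control
        )
        prioritized = interactome.prioritize_interactors(
            interactors, de_cohort, study.protein_gene_map,
            lfc_min=config.apms_lfc_min, fdr_max=config.apms_fdr_max,
        )
        evidence.to_csv(outdir / "apms_evidence.tsv", sep="\t")
        prioritized.round(6).to_csv(outdir / "prioritized_interactors.tsv",
                                    sep="\t", index=False)
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
    report.counts.update(
        interactors=len(interactors), prioritized_interactors=len(prioritized)
    )
    results.update(interactors=interactors, prioritized=prioritized)
    log.info("filter AP-MS: %d proteins -> %d bait-specific -> %d tumor-up",
             len(evidence), len(interactors), len(prioritized))

    # -- stage 5: regulatory triage ----------------------------------------
    stage = "regulatory"
    try:
        de_a = expression.differential_expression(
            study.ko_expr_a, study.ko_labels_a, groups=("control", "ko")
        )
        de_b = expression.differential_expression(
            study.ko_expr_b, study.ko_labels_b, groups=("control", "ko")
        )
        down_a = expression.select_genes(de_a, config.ko_de_lfc_min,
                                         config.ko_de_fdr_max, "down")
        down_b = expression.select_genes(de_b, config.ko_de_lfc_min,
                                         config.ko_de_fdr_max, "down")
        universe = set(de_a.index)
        overlap = expression.fisher_overlap(down_a, down_b, universe,
                                            alternative="greater")
        co_up = down_a & down_b  # down upon knockout = up-regulated by the factor

        gene_models = tr.gene_models(biotype="protein_coding")
        common = regulatory.intersect_peak_sets(
            [study.regulatory.peaks_a, study.regulatory.peaks_b]
        )
        categories = regulatory.annotate_peak_category(
            study.regulatory.peaks_a, gene_models
        )
        assignment = regulatory.assign_peaks_to_genes(
            common, gene_models,
            upstream=config.window_upstream, downstream=config.window_downstream,
        )
        # the triage universe is protein-coding: restrict the tumor-up set
        coding_genes = set(gene_models["gene_id"])
        triage = regulatory.triage_targets(
            co_up_genes=co_up,
            tumor_up_genes=tumor_up & coding_genes,
            common_peak_assignment=assignment,
            gene_effects=study.regulatory.gene_effects,
            effect_threshold=config.effect_threshold,
            required_lines=list(config.fixture.cell_lines),
        )
        de_a.round(6).to_csv(outdir / "de_ko_factor_a.tsv", sep="\t")
        de_b.round(6).to_csv(outdir / "de_ko_factor_b.tsv", sep="\t")
        with open(outdir / "ko_overlap.json", "w") as fh:
            json.dump(dataclasses.asdict(overlap), fh, indent=2, sort_keys=True)
        write_bed6(outdir / "common_peaks.bed", common)
        study.regulatory.peaks_a.assign(category=categories).to_csv(
            outdir / "peak_annotation.tsv", sep="\t", index=False
        )
        assignment.to_csv(outdir / "window_assignment.tsv", sep="\t", index=False)
        with open(outdir / "triage_report.json", "w") as fh:
            json.dump(triage.to_dict(), fh, indent=2, sort_keys=True)
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
    report.counts.update(
        co_up_genes=len(co_up),
        common_peaks=len(common),
        genes_with_window_site=int(assignment["gene_id"].nunique()),
        final_targets=len(triage.final_targets),
    )
    results.update(co_up=co_up, ko_overlap=overlap, common_peaks=common,
                   assignment=assignment, triage=triage)
    log.info("filter triage: %d co-up -> %d final targets",
             len(co_up), len(triage.final_targets))

    report.warnings = list(collector.messages)
    report.to_json(outdir / "run_report.json")
    return report, results
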