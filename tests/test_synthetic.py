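"""Generator contracts: determinism, planted structure, statistical nulls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cryptorf._util import ConfigError
from cryptorf.synthetic import (
    FixtureConfig,
    gen_apms,
    gen_cohort,
    gen_regulatory,
    gen_rpf,
    gen_screen,
    gen_transcriptome,
    generate_study,
    write_study,
)

STOPS = {"TAA", "TAG", "TGA"}


class TestTranscriptome:
    def test_seed_determinism_byte_identical_fasta(self, tmp_path):
        cfg = FixtureConfig(seed=1, n_lnc_transcripts=20, n_coding_transcripts=5)
        for d in ("a", "b"):
            write_study(generate_study(cfg), tmp_path / d)
        fa = (tmp_path / "a" / "transcripts.fa").read_bytes()
        fb = (tmp_path / "b" / "transcripts.fa").read_bytes()
        assert fa == fb

    def test_full_planting_gives_every_lnc_an_atg_stop_orf(self):
        cfg = FixtureConfig(seed=2, n_lnc_transcripts=30, n_coding_transcripts=0,
                            planted_orf_fraction=1.0)
        tr = gen_transcriptome(cfg)
        assert len(tr.planted_orfs) == 30
        for orf in tr.planted_orfs:
            seq = tr.transcripts[orf.transcript_id].seq[orf.start : orf.end]
            assert seq.startswith("ATG")
            assert seq[-3:] in STOPS
            # no internal in-frame stop
            assert all(seq[i : i + 3] not in STOPS for i in range(3, len(seq) - 3, 3))

    def test_planted_orf_translated_length_is_codons_minus_stop(self):
        cfg = FixtureConfig(seed=3, n_lnc_transcripts=10, n_coding_transcripts=0,
                            planted_orf_fraction=1.0)
        tr = gen_transcriptome(cfg)
        for orf in tr.planted_orfs:
            k = (orf.end - orf.start) // 3
            assert k >= 2  # ATG + stop at minimum
            # translated length excluding the stop is k - 1 amino acids
            assert (orf.end - orf.start) % 3 == 0

    def test_zero_transcripts_rejected(self):
        with pytest.raises(ConfigError):
            gen_transcriptome(FixtureConfig(n_lnc_transcripts=0, n_coding_transcripts=0))


class TestRpf:
    def test_periodicity_one_puts_all_planted_psites_in_frame_zero(self):
        cfg = FixtureConfig(seed=4, n_lnc_transcripts=20, n_coding_transcripts=0,
                            planted_orf_fraction=1.0, periodicity=1.0,
                            background_rpf_depth=0)
        tr = gen_transcriptome(cfg)
        ps = gen_rpf(cfg, tr)
        orf_by_tid = {o.transcript_id: o for o in tr.planted_orfs}
        frames = (ps["position"] - ps["transcript_id"].map(
            lambda t: orf_by_tid[t].start)) % 3
        assert (frames == 0).all()

    def test_periodicity_zero_frame_fraction_is_uniform(self):
        # binomial s.e. oracle: with >=10,000 P-sites, |f0 - 1/3| < 3 s.e.
        cfg = FixtureConfig(seed=5, n_lnc_transcripts=60, n_coding_transcripts=0,
                            planted_orf_fraction=1.0, periodicity=0.0,
                            rpf_depth=100, background_rpf_depth=0)
        tr = gen_transcriptome(cfg)
        ps = gen_rpf(cfg, tr)
        orf_by_tid = {o.transcript_id: o for o in tr.planted_orfs}
        frames = (ps["position"] - ps["transcript_id"].map(
            lambda t: orf_by_tid[t].start)) % 3
        n = int(ps["count"].sum())
        assert n >= 10_000
        f0 = float(ps.loc[frames == 0, "count"].sum()) / n
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(f0 - 1 / 3) < 3 * se

    def test_same_seed_identical_psite_table(self):
        cfg = FixtureConfig(seed=6, n_lnc_transcripts=10, n_coding_transcripts=5)
        tr = gen_transcriptome(cfg)
        pd.testing.assert_frame_equal(gen_rpf(cfg, tr), gen_rpf(cfg, tr))


class TestScreen:
    def test_null_depletion_indistinguishable_from_negatives(self):
        # rank-sum oracle on per-guide count means, 1,000 guides per class
        cfg = FixtureConfig(seed=7, depletion_fold=1.0, sgrnas_per_orf=5,
                            n_neg_controls=1000, n_pos_controls=0,
                            essential_orf_fraction=1.0)
        orf_ids = [f"O{i}" for i in range(200)]
        lib, counts, ess = gen_screen(cfg, orf_ids)
        m21 = counts[[c for c in counts if c.startswith("day21")]].mean(axis=1)
        lib = lib.set_index("sgrna_id")
        ess_means = m21[lib["target_orf_id"].isin(ess)]
        neg_means = m21[lib["class"] == "negative_control"]
        p = stats.mannwhitneyu(ess_means, neg_means).pvalue
        assert p > 0.01

    def test_library_composition_at_reference_scale(self):
        # 559 ORFs x 7 guides = 3,913 targeting; 636 positive; 1,064 negative
        cfg = FixtureConfig(seed=8, sgrnas_per_orf=7, n_pos_controls=636,
                            n_neg_controls=1064)
        lib, _, _ = gen_screen(cfg, [f"O{i}" for i in range(559)])
        counts = lib["class"].value_counts()
        assert counts["targeting"] == 3913
        assert counts["positive_control"] == 636
        assert counts["negative_control"] == 1064

    def test_targeting_guides_reference_known_orfs(self):
        cfg = FixtureConfig(seed=9, sgrnas_per_orf=3)
        orf_ids = [f"O{i}" for i in range(20)]
        lib, _, _ = gen_screen(cfg, orf_ids)
        targeting = lib[lib["class"] == "targeting"]
        assert set(targeting["target_orf_id"]) <= set(orf_ids)

    def test_depletion_fold_below_one_rejected(self):
        cfg = FixtureConfig(depletion_fold=0.5)
        with pytest.raises(ConfigError):
            cfg.validate()


class TestCohort:
    def test_zero_planted_lfc_gives_zero_mean_shift(self):
        # t-distribution oracle: mean estimated lfc within 3 s.e. of zero
        cfg = FixtureConfig(seed=10, planted_lfc=0.0, n_tumor=50, n_normal=50,
                            tumor_up_fraction=0.5)
        genes = [f"g{i}" for i in range(100)]
        expr, labels, _, up = gen_cohort(cfg, genes)
        tum = expr.loc[sorted(up), labels[labels == "tumor"].index].mean(axis=1)
        nor = expr.loc[sorted(up), labels[labels == "normal"].index].mean(axis=1)
        lfc = (tum - nor).to_numpy()
        se = lfc.std(ddof=1) / np.sqrt(len(lfc))
        assert abs(lfc.mean()) < 3 * se

    def test_same_seed_identical_survival_table(self):
        cfg = FixtureConfig(seed=11)
        genes = [f"g{i}" for i in range(20)]
        _, _, surv1, _ = gen_cohort(cfg, genes)
        _, _, surv2, _ = gen_cohort(cfg, genes)
        pd.testing.assert_frame_equal(surv1, surv2)

    def test_small_groups_rejected(self):
        with pytest.raises(ConfigError):
            gen_cohort(FixtureConfig(n_tumor=1), ["g1"])


class TestApms:
    def test_true_interactors_bait_specific_by_construction(self):
        cfg = FixtureConfig(seed=12, n_bait_runs=3, n_control_runs=2)
        prots = [f"P{i}" for i in range(50)]
        table, true_set = gen_apms(cfg, prots)
        bait = table[[c for c in table if c.startswith("bait")]]
        ctrl = table[[c for c in table if c.startswith("control")]]
        for pid in true_set:
            assert (bait.loc[pid] >= 2).all()
            assert (ctrl.loc[pid] == 0).all()
        background = table.index.difference(sorted(true_set))
        assert (ctrl.loc[background].max(axis=1) >= 1).all()

    def test_same_seed_identical_tables(self):
        cfg = FixtureConfig(seed=13)
        prots = [f"P{i}" for i in range(30)]
        t1, s1 = gen_apms(cfg, prots)
        t2, s2 = gen_apms(cfg, prots)
        pd.testing.assert_frame_equal(t1, t2)
        assert s1 == s2


@pytest.fixture(scope="module")
def reg_fixture():
    cfg = FixtureConfig(seed=14, n_lnc_transcripts=5, n_coding_transcripts=40)
    tr = gen_transcriptome(cfg)
    gm = tr.gene_models(biotype="protein_coding")
    return cfg, gm, gen_regulatory(cfg, gm)


class TestRegulatory:
    def test_cobound_target_window_contains_common_interval(self, reg_fixture):
        from cryptorf.regulatory import assign_peaks_to_genes, intersect_peak_sets

        _, gm, reg = reg_fixture
        common = intersect_peak_sets([reg.peaks_a, reg.peaks_b])
        assigned = assign_peaks_to_genes(common, gm)
        genes_with_site = set(assigned["gene_id"])
        assert reg.co_bound_target_ids <= genes_with_site

    def test_single_factor_decoy_absent_from_common_assignment(self, reg_fixture):
        from cryptorf.regulatory import assign_peaks_to_genes, intersect_peak_sets

        _, gm, reg = reg_fixture
        common = intersect_peak_sets([reg.peaks_a, reg.peaks_b])
        assigned = assign_peaks_to_genes(common, gm)
        single = {g for g, m in reg.decoys.items() if m == "single_factor"}
        assert single.isdisjoint(set(assigned["gene_id"]))

    def test_same_seed_identical_bed_bytes(self, tmp_path, reg_fixture):
        from cryptorf._util import write_bed6

        cfg, gm, reg = reg_fixture
        reg2 = gen_regulatory(cfg, gm)
        write_bed6(tmp_path / "a.bed", reg.peaks_a)
        write_bed6(tmp_path / "b.bed", reg2.peaks_a)
        assert (tmp_path / "a.bed").read_bytes() == (tmp_path / "b.bed").read_bytes()


class TestStudy:
    def test_ground_truth_ids_exist_in_fixtures(self, study):
        tr = study.transcriptome
        planted_ids = {o.orf_id for o in tr.planted_orfs}
        all_genes = {m.gene_id for m in tr.transcripts.values()}
        assert study.truth.translated_orf_ids == planted_ids
        assert study.truth.essential_orf_ids <= planted_ids
        assert study.truth.tumor_up_gene_ids <= all_genes
        assert study.truth.co_bound_target_ids <= all_genes
        assert study.truth.true_interactor_ids <= set(study.apms.index)

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = FixtureConfig(seed=99, periodicity=0.7, n_tumor=33)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        assert FixtureConfig.from_yaml(tmp_path / "cfg.yaml") == cfg
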