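"""Naive aligner, acceptance thresholds, target resolution, SSR mining."""

import numpy as np
import pytest

from carpmap.anchoring import (
    filter_anchor_hits,
    find_ssr_motifs,
    hit_reject_reason,
    naive_align,
    resolve_targets,
    select_candidate_loci,
)
from carpmap.dataio import (
    AlignmentHit,
    PhysicalContig,
    PhysicalMap,
    PipelineConfig,
)
from carpmap.pipeline import run_anchoring


def _rand_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestNaiveAlign:
    def test_verbatim_embedding_gives_perfect_hit(self):
        rng = np.random.default_rng(0)
        q = _rand_seq(rng, 200)
        bes = {"c1.f": _rand_seq(rng, 150) + q + _rand_seq(rng, 150)}
        hits = naive_align("m", q, bes)
        assert len(hits) == 1
        h = hits[0]
        assert h.identity_pct == 100.0
        assert h.align_len == 200
        assert h.strand == "+"
        assert h.subject_interval() == (150, 350)

    def test_absent_query_gives_no_hits(self):
        rng = np.random.default_rng(1)
        hits = naive_align("m", _rand_seq(rng, 200), {"c1.f": _rand_seq(rng, 700)})
        assert hits == []

    def test_three_substitutions_in_200bp(self):
        rng = np.random.default_rng(2)
        q = _rand_seq(rng, 200)
        mutated = list(q)
        for pos in (40, 100, 160):
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        bes = {"c1.f": _rand_seq(rng, 100) + "".join(mutated) + _rand_seq(rng, 100)}
        h = naive_align("m", q, bes)[0]
        assert h.align_len == 200
        assert h.identity_pct == pytest.approx(98.5)
        assert h.mismatch == 3

    def test_minus_strand_reported_blast_style(self):
        rng = np.random.default_rng(3)
        q = _rand_seq(rng, 180)
        bes = {"c1.r": _rand_seq(rng, 60) + _revcomp(q) + _rand_seq(rng, 60)}
        h = naive_align("m", q, bes)[0]
        assert h.strand == "-"
        assert h.subject_start > h.subject_end
        assert h.align_len == 180
        assert h.identity_pct == 100.0

    def test_empty_query_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            naive_align("m", "", {"c1.f": "ACGT" * 100})


class TestThresholds:
    def _hit(self, length, ident, evalue=0.0):
        return AlignmentHit("m", "c.f", ident, length, 0, 0, 1, length, 1, length,
                            evalue, 2.0 * length)

    def test_ssr_above_both_thresholds_accepted(self, cfg):
        assert hit_reject_reason(self._hit(160, 96.0), "SSR", cfg) == "none"

    def test_ssr_short_hit_rejected_below_length(self, cfg):
        assert hit_reject_reason(self._hit(140, 99.0), "SSR", cfg) == "below_length"

    def test_snp_identity_boundary_is_strict(self, cfg):
        # exactly 95.0% fails the "greater than 95%" rule
        assert hit_reject_reason(self._hit(100, 95.0), "SNP", cfg) == "below_identity"
        assert hit_reject_reason(self._hit(100, 95.1), "SNP", cfg) == "none"

    def test_snp_length_boundary_inclusive(self, cfg):
        assert hit_reject_reason(self._hit(100, 99.0), "SNP", cfg) == "none"
        assert hit_reject_reason(self._hit(99, 99.0), "SNP", cfg) == "below_length"

    def test_evalue_cutoff(self, cfg):
        assert hit_reject_reason(self._hit(200, 99.0, evalue=1e-3), "SSR", cfg) == "above_evalue"

    @pytest.mark.parametrize("threshold", [100, 150, 200, 250])
    def test_filtering_monotone_in_length_threshold(self, threshold):
        hits = [self._hit(l, 97.0) for l in range(90, 260, 10)]
        lo = filter_anchor_hits(hits, "SSR", PipelineConfig(ssr_min_align_bp=threshold))
        hi = filter_anchor_hits(hits, "SSR", PipelineConfig(ssr_min_align_bp=threshold + 50))
        assert {id(h) for h in hi} <= {id(h) for h in lo}


class TestResolveTargets:
    @pytest.fixture()
    def pm(self):
        return PhysicalMap(
            [PhysicalContig("850", 300, frozenset({"CYC037J02"}))],
            frozenset({"LONE1"}),
        )

    def _hit(self, bes, bitscore=400.0):
        return AlignmentHit("m", bes, 99.0, 200, 2, 0, 1, 200, 1, 200, 0.0, bitscore)

    def test_clone_in_contig_anchors_contig(self, pm, cfg):
        anchors, issues = resolve_targets(
            {"HLJ1147": [self._hit("CYC037J02.r")]}, {"HLJ1147": "SSR"}, pm, cfg
        )
        a = anchors[0]
        assert (a.target_kind, a.target_id, a.accepted) == ("contig", "850", True)
        assert a.clone_id == "CYC037J02"

    def test_singleton_clone_anchors_single_bac(self, pm, cfg):
        anchors, _ = resolve_targets(
            {"m": [self._hit("LONE1.f")]}, {"m": "SSR"}, pm, cfg
        )
        assert anchors[0].target_kind == "single_bac"
        assert anchors[0].target_id == "LONE1"

    def test_unknown_clone_reported_unresolved(self, pm, cfg):
        anchors, issues = resolve_targets(
            {"m": [self._hit("NOWHERE.f")]}, {"m": "SSR"}, pm, cfg
        )
        assert anchors == []
        assert issues[0]["issue"] == "unresolved_clone"

    def test_equal_best_on_two_contigs_assigned_to_neither(self, cfg):
        pm = PhysicalMap(
            [
                PhysicalContig("c1", 100, frozenset({"A"})),
                PhysicalContig("c2", 100, frozenset({"B"})),
            ]
        )
        anchors, issues = resolve_targets(
            {"m": [self._hit("A.f"), self._hit("B.f")]}, {"m": "SSR"}, pm, cfg
        )
        assert anchors == []
        assert issues[0]["issue"] == "ambiguous_equal_best"

    def test_better_hit_wins_and_conflict_logged(self, cfg):
        pm = PhysicalMap(
            [
                PhysicalContig("c1", 100, frozenset({"A"})),
                PhysicalContig("c2", 100, frozenset({"B"})),
            ]
        )
        anchors, issues = resolve_targets(
            {"m": [self._hit("A.f", 500.0), self._hit("B.f", 400.0)]},
            {"m": "SSR"}, pm, cfg,
        )
        assert anchors[0].target_id == "c1"
        assert issues[0]["issue"] == "secondary_targets"

    def test_rejected_marker_carries_reason(self, pm, cfg):
        short = AlignmentHit("m", "CYC037J02.r", 99.0, 140, 1, 0, 1, 140, 1, 140, 0.0, 280.0)
        anchors, _ = resolve_targets({"m": [short]}, {"m": "SSR"}, pm, cfg)
        assert not anchors[0].accepted
        assert anchors[0].reject_reason == "below_length"


class TestEndToEndRecovery:
    def test_all_embedded_markers_recovered(self, clean_sim, cfg):
        res = run_anchoring(clean_sim.marker_seqs, clean_sim.bes, clean_sim.pm, cfg)
        got = {(a.marker_id, a.target_kind, a.target_id) for a in res.anchors if a.accepted}
        want = {
            (r.marker_id, r.target_kind, r.target_id)
            for r in clean_sim.anchor_truth.itertuples()
        }
        assert want <= got  # recall 1.0
        assert got == want  # precision 1.0: nothing spurious


class TestSsrMining:
    def test_centered_dinucleotide_selected(self, cfg):
        rng = np.random.default_rng(4)
        seq = _rand_seq(rng, 80) + "CA" * 10 + _rand_seq(rng, 100)
        pm = PhysicalMap([PhysicalContig("big", 800, frozenset({"K1"}))])
        df = select_candidate_loci(pm, {"K1.f": seq}, cfg)
        assert len(df) == 1
        assert df.iloc[0].unit in ("CA", "AC")
        # flanking bases may extend the maximal repeat by a unit or so
        assert df.iloc[0].repeat_len >= 20

    def test_motif_near_read_end_rejected(self, cfg):
        rng = np.random.default_rng(5)
        seq = _rand_seq(rng, 10) + "AG" * 10 + _rand_seq(rng, 170)
        pm = PhysicalMap([PhysicalContig("big", 800, frozenset({"K1"}))])
        assert select_candidate_loci(pm, {"K1.f": seq}, cfg).empty

    def test_small_contig_excluded_entirely(self, cfg):
        rng = np.random.default_rng(6)
        seq = _rand_seq(rng, 80) + "CA" * 10 + _rand_seq(rng, 100)
        pm = PhysicalMap([PhysicalContig("small", 600, frozenset({"K1"}))])
        # 600 CB * 1.428 kb = 857 kb < 1 Mb
        assert select_candidate_loci(pm, {"K1.f": seq}, cfg).empty

    def test_at_most_two_loci_per_contig(self, cfg):
        rng = np.random.default_rng(7)
        seqs = {
            f"K{i}.f": _rand_seq(rng, 60) + "ACT" * 6 + _rand_seq(rng, 60)
            for i in range(3)
        }
        pm = PhysicalMap([PhysicalContig("big", 800, frozenset({"K0", "K1", "K2"}))])
        assert len(select_candidate_loci(pm, seqs, cfg)) == 2

    def test_homopolymers_not_reported(self):
        assert find_ssr_motifs("A" * 40) == []
        assert find_ssr_motifs("C" * 6 + "AT" * 8 + "G" * 6) == [(6, 22, "AT")]
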