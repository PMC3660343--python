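"""Reference placement, homology assignment, block merging, segmental loss."""

import numpy as np
import pytest

from carpmap.dataio import AlignmentHit, PipelineConfig
from carpmap.synteny import (
    ReferencePlacement,
    assign_lg_homology,
    detect_segmental_loss,
    mate_pair_consistency,
    merge_synteny_blocks,
    place_queries,
    two_to_one_summary,
)
from carpmap.pipeline import bes_source_map, run_anchoring, run_integration, run_synteny
from carpmap.simdata import (
    SimConfig,
    chromosome_lengths,
    simulate_physical_and_bes,
    simulate_reference_placements,
    simulate_true_genome,
)

from conftest import anchors_from_truth, true_map_from_genome


def _hit(query, chrom, start, end, evalue=1e-20, bitscore=400.0):
    return AlignmentHit(query, chrom, 99.0, abs(end - start) + 1, 0, 0, 1,
                        abs(end - start) + 1, start, end, evalue, bitscore)


def _placement(query, lg, chrom, start, end, cm=0.0):
    return ReferencePlacement(query, chrom, start, end, "+", 1e-20, 400.0, lg, cm)


class TestPlaceQueries:
    def test_top_hit_below_cutoff_kept(self, cfg):
        hits = [_hit("q", "chr1", 100, 300, evalue=1e-3, bitscore=100.0),
                _hit("q", "chr2", 100, 300, evalue=1e-8, bitscore=90.0)]
        placements = place_queries(hits, cfg)
        assert len(placements) == 1
        assert placements[0].chromosome == "chr2"

    def test_equal_bitscore_tie_breaks_to_first_chromosome(self, cfg):
        hits = [_hit("q", "chr5", 100, 300), _hit("q", "chr2", 100, 300)]
        assert place_queries(hits, cfg)[0].chromosome == "chr2"

    def test_coordinates_zero_based_half_open(self, cfg):
        p = place_queries([_hit("q", "chr1", 101, 200)], cfg)[0]
        assert (p.start, p.end) == (100, 200)
        minus = place_queries([_hit("q2", "chr1", 200, 101)], cfg)[0]
        assert (minus.start, minus.end, minus.strand) == (100, 200, "-")

    def test_simulated_placements_recover_true_chromosome(self, clean_sim, cfg):
        truth_chrom = dict(zip(clean_sim.ref_truth.bes_id, clean_sim.ref_truth.chromosome))
        placements = place_queries(clean_sim.ref_hits, cfg)
        good = sum(p.chromosome == truth_chrom[p.query_id] for p in placements)
        assert good / len(placements) >= 0.99


class TestHomology:
    def test_modal_chromosome_with_fraction(self, cfg):
        placements = [
            _placement(f"b{i}.f", "LG1", "chr1" if i < 8 else "chr5", i * 10, i * 10 + 5)
            for i in range(10)
        ]
        assignments, unassigned = assign_lg_homology(placements, cfg)
        a = assignments[0]
        assert (a.lg_id, a.chromosome, a.supporting_hits, a.fraction) == ("LG1", "chr1", 8, 0.8)
        assert unassigned == []

    def test_lg_without_placements_unassigned(self, cfg):
        assignments, unassigned = assign_lg_homology(
            [_placement("b.f", "LG1", "chr1", 0, 5)], cfg
        )
        assert [a.lg_id for a in assignments] == ["LG1"]

    def test_below_fraction_threshold_unassigned(self, cfg):
        placements = [
            _placement(f"b{i}.f", "LG1", f"chr{i}", 0, 5) for i in range(4)
        ]
        assignments, unassigned = assign_lg_homology(placements, cfg)
        assert assignments == []
        assert unassigned == ["LG1"]

    def test_two_to_one_on_simulated_genome(self, clean_sim, cfg):
        src = {
            r.bes_id: (r.lg_id, r.cM) for r in clean_sim.ref_truth.itertuples()
        }
        res = run_synteny(clean_sim.ref_hits, src, cfg, clean_sim.chrom_len)
        assert len(res.two_to_one) == 2
        assert res.two_to_one.is_two_to_one.all()


class TestBlockMerging:
    def test_gap_rule_merges_and_splits(self, cfg):
        near = [
            _placement("a.f", "LG1", "chr1", 1_000_000, 1_000_400, 1.0),
            _placement("b.f", "LG1", "chr1", 1_500_000, 1_500_400, 2.0),
            _placement("c.f", "LG1", "chr1", 2_200_000, 2_200_400, 3.0),
        ]
        blocks = merge_synteny_blocks(near, cfg)
        assert len(blocks) == 1
        assert blocks[0].n_support == 3
        assert (blocks[0].cM_start, blocks[0].cM_end) == (1.0, 3.0)

        far = near[:1] + [_placement("d.f", "LG1", "chr1", 5_000_000, 5_000_400, 9.0)]
        assert len(merge_synteny_blocks(far, cfg)) == 2

    def test_single_hit_block(self, cfg):
        blocks = merge_synteny_blocks([_placement("a.f", "LG1", "chr1", 10, 500)], cfg)
        assert len(blocks) == 1
        assert (blocks[0].bp_start, blocks[0].bp_end, blocks[0].n_support) == (10, 500, 1)

    def test_merging_is_idempotent(self, clean_sim, cfg):
        src = {r.bes_id: (r.lg_id, r.cM) for r in clean_sim.ref_truth.itertuples()}
        placements = place_queries(clean_sim.ref_hits, cfg, src)
        blocks = merge_synteny_blocks(placements, cfg)
        as_placements = [
            ReferencePlacement(f"blk{i}.f", b.chromosome, b.bp_start, b.bp_end, "+",
                               0.0, 1.0, b.lg_id, b.cM_start)
            for i, b in enumerate(blocks)
        ]
        again = merge_synteny_blocks(as_placements, cfg)
        assert [(b.lg_id, b.chromosome, b.bp_start, b.bp_end) for b in again] == [
            (b.lg_id, b.chromosome, b.bp_start, b.bp_end) for b in blocks
        ]

    def test_support_counts_sum_to_placements(self, clean_sim, cfg):
        src = {r.bes_id: (r.lg_id, r.cM) for r in clean_sim.ref_truth.itertuples()}
        placements = place_queries(clean_sim.ref_hits, cfg, src)
        blocks = merge_synteny_blocks(placements, cfg)
        per_lg_blocks: dict[str, int] = {}
        for b in blocks:
            per_lg_blocks[b.lg_id] = per_lg_blocks.get(b.lg_id, 0) + b.n_support
        per_lg_placed: dict[str, int] = {}
        for p in placements:
            per_lg_placed[p.source_lg] = per_lg_placed.get(p.source_lg, 0) + 1
        assert per_lg_blocks == per_lg_placed

    def test_shrinking_gap_never_merges_more(self, clean_sim):
        src = {r.bes_id: (r.lg_id, r.cM) for r in clean_sim.ref_truth.itertuples()}
        counts = []
        for gap in (2_000_000, 1_000_000, 500_000, 100_000):
            cfg = PipelineConfig(synteny_max_gap_bp=gap)
            placements = place_queries(clean_sim.ref_hits, cfg, src)
            counts.append(len(merge_synteny_blocks(placements, cfg)))
        assert counts == sorted(counts)


@pytest.fixture(scope="module")
def dense_loss_sim():
    """Two homeologous LGs with dense BES tiling; half of TLG1's chromosome
    share removed as a segmental-loss interval."""
    sim = SimConfig(
        n_lgs=2, markers_per_lg=60, n_contigs=80, clones_per_contig=4,
        cb_length_range=(300, 800), dup_marker_count=0, decoy_rate=0.0,
        loss_fractions={"TLG1": 0.5}, seed=31,
    )
    genome = simulate_true_genome(sim)
    pm, _, _, truth = simulate_physical_and_bes(genome, sim)
    hits, ref_truth = simulate_reference_placements(genome, sim, pm, truth)
    src = {r.bes_id: (r.lg_id, r.cM) for r in ref_truth.itertuples()}
    return sim, genome, hits, src, chromosome_lengths(genome, sim)


class TestSegmentalLoss:

    def test_half_lost_lg_covers_about_half(self, dense_loss_sim, cfg):
        sim, genome, hits, src, chrom_len = dense_loss_sim
        res = run_synteny(hits, src, cfg, chrom_len)
        frac = {r.lg_id: r.covered_fraction for r in res.loss.itertuples()}
        assert frac["TLG1"] == pytest.approx(0.5, abs=0.05)
        assert res.loss.set_index("lg_id").candidate_loss["TLG1"]

    def test_full_coverage_not_flagged(self, dense_loss_sim, cfg):
        sim, genome, hits, src, chrom_len = dense_loss_sim
        res = run_synteny(hits, src, cfg, chrom_len)
        row = res.loss.set_index("lg_id").loc["TLG2"]
        assert row.covered_fraction >= 0.95
        assert not row.candidate_loss

    def test_lg_without_placements_flagged_zero(self, cfg):
        from carpmap.synteny import HomologyAssignment

        df = detect_segmental_loss(
            [HomologyAssignment("LGx", "chr9", 3, 1.0)], [], {"chr9": 1000}
        )
        assert df.iloc[0].covered_fraction == 0.0
        assert df.iloc[0].candidate_loss


class TestMatePairs:
    def test_consistency_diagnostic(self):
        placements = [
            _placement("A.f", "LG1", "chr1", 0, 10),
            _placement("A.r", "LG1", "chr1", 100, 110),
            _placement("B.f", "LG1", "chr1", 0, 10),
            _placement("B.r", "LG1", "chr2", 0, 10),
            _placement("C.f", "LG1", "chr1", 0, 10),
        ]
        df = mate_pair_consistency(placements)
        assert len(df) == 2  # C has only one end placed
        assert df.set_index("clone_id").consistent.to_dict() == {"A": True, "B": False}


class TestFullSimPipeline:
    def test_end_to_end_through_real_stages(self, clean_sim, cfg):
        """linkage -> anchoring -> integration -> synteny on clean data."""
        from carpmap.pipeline import run_linkage

        lr = run_linkage(clean_sim.family, cfg)
        ar = run_anchoring(clean_sim.marker_seqs, clean_sim.bes, clean_sim.pm, cfg)
        ir = run_integration(lr.gmap, ar.anchors, clean_sim.pm, cfg)
        assert ir.error_rate_pct == 0
        src = bes_source_map(ir.imap, clean_sim.pm)
        res = run_synteny(clean_sim.ref_hits, src, cfg, clean_sim.chrom_len)
        # every contig's BES inherit an LG, so homology is assignable
        assert len(res.assignments) >= 3
        assert (res.two_to_one.n_lgs <= 2).all()
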