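"""Comparative mapping of the integrated map against a diploid reference.

BES and marker sequences are placed on reference chromosomes by their single
top BLAST hit (e-value <= cutoff, ties broken deterministically), each
placement tagged with its source linkage group.  Per LG, the modal
chromosome with at least half the placements defines the homology
assignment; under a lineage-specific whole-genome duplication every
reference chromosome should collect exactly two LGs.  Collinear placements
are merged into synteny blocks while the reference-coordinate gap stays
under 1 Mb, and each LG's merged block span over its homologous chromosome
measures candidate segmental loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dataio import AlignmentHit, PipelineConfig, clone_of_bes

__all__ = [
    "ReferencePlacement",
    "HomologyAssignment",
    "SyntenyBlock",
    "place_queries",
    "assign_lg_homology",
    "two_to_one_summary",
    "merge_synteny_blocks",
    "detect_segmental_loss",
    "mate_pair_consistency",
    "blocks_to_bed",
    "plot_blocks",
]


@dataclass
class ReferencePlacement:
    query_id: str
    chromosome: str
    start: int  # 0-based half-open
    end: int
    strand: str
    evalue: float
    bitscore: float
    source_lg: str | None = None
    source_cM: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.query_id}: empty reference interval")


@dataclass
class HomologyAssignment:
    lg_id: str
    chromosome: str
    supporting_hits: int
    fraction: float


@dataclass
class SyntenyBlock:
    lg_id: str
    chromosome: str
    bp_start: int
    bp_end: int
    cM_start: float
    cM_end: float
    n_support: int


def place_queries(
    hits: list[AlignmentHit],
    cfg: PipelineConfig,
    source_map: dict[str, tuple[str, float]] | None = None,
) -> list[ReferencePlacement]:
    """Single top placement per query.

    Hits above the e-value cutoff are discarded; among the rest the top hit
    is chosen by (bitscore desc, evalue asc, chromosome asc, start asc).
    ``source_map`` maps a query id to its (linkage group, cM) on the
    integrated map; unmapped queries get source_lg None.
    """
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        if h.evalue <= cfg.evalue_cutoff:
            by_query.setdefault(h.query_id, []).append(h)
    placements: list[ReferencePlacement] = []
    for query in sorted(by_query):
        best = min(
            by_query[query],
            key=lambda h: (-h.bitscore, h.evalue, h.subject_id, h.subject_interval()[0]),
        )
        start, end = best.subject_interval()
        src = (source_map or {}).get(query)
        placements.append(
            ReferencePlacement(
                query, best.subject_id, start, end, best.strand,
                best.evalue, best.bitscore,
                source_lg=src[0] if src else None,
                source_cM=src[1] if src else None,
            )
        )
    return placements


def assign_lg_homology(
    placements: list[ReferencePlacement], cfg: PipelineConfig
) -> tuple[list[HomologyAssignment], list[str]]:
    """Per-LG modal reference chromosome with its supporting fraction.

    An assignment is emitted only when the modal fraction reaches
    ``homology_min_fraction``.  Returns (assignments, LGs with no placements
    or below threshold)."""
    counts: dict[str, dict[str, int]] = {}
    for p in placements:
        if p.source_lg is None:
            continue
        counts.setdefault(p.source_lg, {}).setdefault(p.chromosome, 0)
        counts[p.source_lg][p.chromosome] += 1
    assignments: list[HomologyAssignment] = []
    unassigned: list[str] = []
    for lg in sorted(counts):
        per_chrom = counts[lg]
        total = sum(per_chrom.values())
        chrom, n = min(per_chrom.items(), key=lambda kv: (-kv[1], kv[0]))
        frac = n / total
        if frac >= cfg.homology_min_fraction:
            assignments.append(HomologyAssignment(lg, chrom, n, round(frac, 4)))
        else:
            unassigned.append(lg)
    return assignments, unassigned


def two_to_one_summary(assignments: list[HomologyAssignment]) -> pd.DataFrame:
    """Per chromosome: the list of assigned LGs and whether there are
    exactly two (the duplication signature)."""
    per_chrom: dict[str, list[str]] = {}
    for a in assignments:
        per_chrom.setdefault(a.chromosome, []).append(a.lg_id)
    rows = [
        {
            "chromosome": chrom,
            "lg_list": ",".join(sorted(lgs)),
            "n_lgs": len(lgs),
            "is_two_to_one": len(lgs) == 2,
        }
        for chrom, lgs in sorted(per_chrom.items())
    ]
    return pd.DataFrame(rows)


def merge_synteny_blocks(
    placements: list[ReferencePlacement], cfg: PipelineConfig
) -> list[SyntenyBlock]:
    """Merge consecutive same-LG placements on one chromosome while the bp
    gap stays <= synteny_max_gap_bp.  Single-placement blocks are allowed.
    Idempotent: re-merging the merged blocks changes nothing."""
    tagged = [p for p in placements if p.source_lg is not None]
    tagged.sort(key=lambda p: (p.source_lg, p.chromosome, p.start, p.end, p.query_id))
    blocks: list[SyntenyBlock] = []
    cur: SyntenyBlock | None = None
    for p in tagged:
        cm = p.source_cM if p.source_cM is not None else 0.0
        if (
            cur is not None
            and p.source_lg == cur.lg_id
            and p.chromosome == cur.chromosome
            and p.start - cur.bp_end <= cfg.synteny_max_gap_bp
        ):
            cur.bp_end = max(cur.bp_end, p.end)
            cur.cM_start = min(cur.cM_start, cm)
            cur.cM_end = max(cur.cM_end, cm)
            cur.n_support += 1
        else:
            cur = SyntenyBlock(p.source_lg, p.chromosome, p.start, p.end, cm, cm, 1)
            blocks.append(cur)
    return blocks


def detect_segmental_loss(
    assignments: list[HomologyAssignment],
    blocks: list[SyntenyBlock],
    chromosome_lengths: dict[str, int] | None = None,
    placements: list[ReferencePlacement] | None = None,
    flag_below: float = 0.8,
) -> pd.DataFrame:
    """Per assigned LG: fraction of its homologous chromosome covered by its
    merged synteny blocks; LGs below ``flag_below`` are candidate segmental
    losses.  Chromosome lengths come from the supplied table or, failing
    that, the maximum placement end on each chromosome."""
    if chromosome_lengths is None:
        chromosome_lengths = {}
        for p in placements or []:
            chromosome_lengths[p.chromosome] = max(
                chromosome_lengths.get(p.chromosome, 0), p.end
            )
    rows = []
    for a in assignments:
        clen = chromosome_lengths.get(a.chromosome, 0)
        covered = sum(
            b.bp_end - b.bp_start
            for b in blocks
            if b.lg_id == a.lg_id and b.chromosome == a.chromosome
        )
        frac = covered / clen if clen else 0.0
        rows.append(
            {
                "lg_id": a.lg_id,
                "chromosome": a.chromosome,
                "covered_bp": covered,
                "chromosome_bp": clen,
                "covered_fraction": round(frac, 4),
                "candidate_loss": frac < flag_below,
            }
        )
    return pd.DataFrame(rows)


def mate_pair_consistency(placements: list[ReferencePlacement]) -> pd.DataFrame:
    """Diagnostic: for clones with both ends placed, do the two ends land on
    the same chromosome?  Reported, not used as a filter."""
    by_clone: dict[str, dict[str, str]] = {}
    for p in placements:
        if p.query_id.endswith(".f") or p.query_id.endswith(".r"):
            by_clone.setdefault(clone_of_bes(p.query_id), {})[p.query_id[-1]] = p.chromosome
    rows = []
    for clone in sorted(by_clone):
        ends = by_clone[clone]
        if len(ends) == 2:
            rows.append(
                {
                    "clone_id": clone,
                    "chrom_f": ends["f"],
                    "chrom_r": ends["r"],
                    "consistent": ends["f"] == ends["r"],
                }
            )
    return pd.DataFrame(rows)


def blocks_to_bed(blocks: list[SyntenyBlock], path) -> None:
    """Write blocks as BED (0-based half-open reference coordinates)."""
    lines = [
        f"{b.chromosome}\t{b.bp_start}\t{b.bp_end}\t{b.lg_id}\t{b.n_support}\t+"
        for b in sorted(blocks, key=lambda b: (b.chromosome, b.bp_start))
    ]
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def plot_blocks(blocks: list[SyntenyBlock], path) -> None:
    """One horizontal track per chromosome; blocks colored by source LG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted({b.chromosome for b in blocks})
    lgs = sorted({b.lg_id for b in blocks})
    cmap = plt.get_cmap("tab20")
    fig, ax = plt.subplots(figsize=(9, 0.6 * max(len(chroms), 1) + 1.5))
    for y, chrom in enumerate(chroms):
        for b in blocks:
            if b.chromosome != chrom:
                continue
            ax.barh(
                y,
                (b.bp_end - b.bp_start) / 1e6,
                left=b.bp_start / 1e6,
                height=0.6,
                color=cmap(lgs.index(b.lg_id) % 20),
                edgecolor="none",
            )
    ax.set_yticks(range(len(chroms)), chroms)
    ax.set_xlabel("reference position (Mb)")
    ax.set_title("synteny blocks by source linkage group")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
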