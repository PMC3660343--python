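"""End-to-end stage drivers shared by the CLI, the analysis scripts and the
tests: each function takes in-memory objects, runs one pipeline stage and
returns plain results; the ``run_*_files`` variants add file I/O around
them."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import anchoring, integration, linkage, synteny
from .dataio import (
    GenotypeTable,
    PhysicalMap,
    PipelineConfig,
    read_blast_tab,
    read_fasta,
    read_genotypes,
    read_physical_map,
)

__all__ = [
    "LinkageResult",
    "AnchoringResult",
    "IntegrationResult",
    "SyntenyResult",
    "run_linkage",
    "run_anchoring",
    "run_integration",
    "run_synteny",
    "bes_source_map",
]


@dataclass
class LinkageResult:
    gmap: linkage.GeneticMap
    stats: pd.DataFrame
    lod_sweep: dict[float, int]
    diagnostics: dict


def run_linkage(table: GenotypeTable, cfg: PipelineConfig) -> LinkageResult:
    gmap, diag = linkage.build_genetic_map(table, cfg)
    return LinkageResult(gmap, linkage.map_stats(gmap), diag["lod_sweep"], diag)


@dataclass
class AnchoringResult:
    anchors: list[anchoring.MarkerAnchor]
    issues: list[dict]
    hits_by_marker: dict[str, list]


def run_anchoring(
    marker_seqs: dict[str, str],
    bes_set: dict[str, str],
    pm: PhysicalMap,
    cfg: PipelineConfig,
    marker_types: dict[str, str] | None = None,
    blast_hits: list | None = None,
) -> AnchoringResult:
    """Anchor markers to the physical map; ``blast_hits`` (BLAST tabular)
    replaces the built-in aligner when supplied."""
    hits = blast_hits if blast_hits is not None else anchoring.align_markers(marker_seqs, bes_set)
    by_marker: dict[str, list] = {}
    for h in hits:
        by_marker.setdefault(h.query_id, []).append(h)
    if marker_types is None:
        marker_types = {
            m: ("SNP" if m.upper().startswith("SNP") else "SSR") for m in by_marker
        }
    anchors, issues = anchoring.resolve_targets(by_marker, marker_types, pm, cfg)
    return AnchoringResult(anchors, issues, by_marker)


@dataclass
class IntegrationResult:
    imap: integration.IntegratedMap
    coverage: integration.CoverageReport
    conflicting_contigs: list[str]
    error_rate_pct: int
    table: pd.DataFrame


def run_integration(
    gmap: linkage.GeneticMap,
    anchors: list[anchoring.MarkerAnchor],
    pm: PhysicalMap,
    cfg: PipelineConfig,
) -> IntegrationResult:
    imap = integration.integrate(gmap, anchors, pm, cfg)
    coverage = integration.physical_coverage(imap, cfg)
    conflicting, rate = integration.detect_conflicts(imap)
    return IntegrationResult(imap, coverage, conflicting, rate,
                             integration.integrated_map_table(imap))


def bes_source_map(
    imap: integration.IntegratedMap, pm: PhysicalMap
) -> dict[str, tuple[str, float]]:
    """Map every BES id of every integrated contig/BAC to that element's
    (LG, cM) so reference hits can be tagged with their source LG."""
    out: dict[str, tuple[str, float]] = {}
    clone_map: dict[str, tuple[str, float]] = {}
    for e in imap.elements:
        if e.element_kind == "contig":
            contig = pm.contig(e.element_id)
            for clone in contig.clone_ids:
                clone_map[clone] = (e.lg_id, e.position_cM)
        else:
            clone_map[e.element_id] = (e.lg_id, e.position_cM)
    for clone, src in clone_map.items():
        out[f"{clone}.f"] = src
        out[f"{clone}.r"] = src
    return out


@dataclass
class SyntenyResult:
    placements: list[synteny.ReferencePlacement]
    assignments: list[synteny.HomologyAssignment]
    unassigned_lgs: list[str]
    blocks: list[synteny.SyntenyBlock]
    two_to_one: pd.DataFrame
    loss: pd.DataFrame
    mate_pairs: pd.DataFrame


def run_synteny(
    hits: list,
    source_map: dict[str, tuple[str, float]],
    cfg: PipelineConfig,
    chromosome_lengths: dict[str, int] | None = None,
) -> SyntenyResult:
    placements = synteny.place_queries(hits, cfg, source_map)
    assignments, unassigned = synteny.assign_lg_homology(placements, cfg)
    blocks = synteny.merge_synteny_blocks(placements, cfg)
    return SyntenyResult(
        placements,
        assignments,
        unassigned,
        blocks,
        synteny.two_to_one_summary(assignments),
        synteny.detect_segmental_loss(
            assignments, blocks, chromosome_lengths, placements
        ),
        synteny.mate_pair_consistency(placements),
    )
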