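"""Attach anchored contigs and single BACs to linkage-group positions and do
the integration bookkeeping: physical coverage (redundant and non-redundant),
assembly-conflict detection, orientability, and duplicated-marker classes.

Length conventions: a contig's physical length is cb_length * kb_per_cb
(1.428 kb per consensus band by default); a single BAC counts the mean
insert length (141 kb).  Lengths are kept exact in kb internally and
formatted to 2-decimal Mb only at report time.  A contig anchored on two
linkage groups contributes to each LG's (redundant) sum but only once to
the non-redundant total; that contig is flagged as a conflict — evidence of
either a physical-map assembly error or, at times, a duplicated region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anchoring import MarkerAnchor
from .dataio import PhysicalMap, PipelineConfig
from .linkage import GeneticMap

__all__ = [
    "IntegratedElement",
    "IntegratedMap",
    "CoverageReport",
    "DuplicatedMarkerPair",
    "integrate",
    "physical_coverage",
    "detect_conflicts",
    "classify_duplicated_markers",
    "duplicated_pairs_from_map",
    "integrated_map_table",
]

INTRA_LG_SPAN_WARN_CM = 20.0


@dataclass
class IntegratedElement:
    """One contig or single BAC attached to one linkage group."""

    lg_id: str
    element_kind: str  # "contig" | "single_bac"
    element_id: str
    markers: list[tuple[str, float]]  # (marker_id, position_cM)
    length_kb: float
    orientable: bool = False
    orientation: str = "unoriented"  # forward | reverse | unoriented
    conflict: bool = False

    @property
    def position_cM(self) -> float:
        return min(p for _, p in self.markers)


@dataclass
class IntegratedMap:
    elements: list[IntegratedElement]
    unplaced_anchors: list[MarkerAnchor] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def by_lg(self) -> dict[str, list[IntegratedElement]]:
        out: dict[str, list[IntegratedElement]] = {}
        for e in self.elements:
            out.setdefault(e.lg_id, []).append(e)
        return out

    def element_lgs(self, element_id: str) -> list[str]:
        return sorted({e.lg_id for e in self.elements if e.element_id == element_id})


@dataclass
class CoverageReport:
    per_lg_mb: dict[str, float]  # redundant, per LG
    total_redundant_mb: float
    total_nonredundant_mb: float
    contig_mb_nonredundant: float
    single_bac_mb: float
    n_contigs_nonredundant: int
    n_single_bacs: int
    genome_fraction: float


@dataclass
class DuplicatedMarkerPair:
    base_id: str
    lg_a: str
    lg_b: str
    classification: str  # "wgd_consistent" | "intra_lg"
    orthologous_chromosome: str | None = None

    def __post_init__(self) -> None:
        same = self.lg_a == self.lg_b
        if (self.classification == "intra_lg") != same:
            raise ValueError("classification inconsistent with linkage groups")


def integrate(
    gmap: GeneticMap,
    anchors: list[MarkerAnchor],
    pm: PhysicalMap,
    cfg: PipelineConfig,
) -> IntegratedMap:
    """Attach every accepted anchor's target at its marker's map position.

    Anchors whose marker is not on the map are reported unplaced, not
    attached.  Elements with >= 2 markers on one LG are orientable (the
    orientation itself stays unoriented: contig-internal BES coordinates are
    not part of the physical-map record).  Elements anchored on two or more
    LGs are flagged as conflicts; a wide (> 20 cM) intra-LG marker span is a
    warning only.
    """
    marker_pos = gmap.marker_to_lg()
    contig_kb = {c.contig_id: c.cb_length * cfg.kb_per_cb for c in pm.contigs}

    grouped: dict[tuple[str, str, str], list[tuple[str, float]]] = {}
    unplaced: list[MarkerAnchor] = []
    for a in anchors:
        if not a.accepted:
            continue
        if a.target_kind == "contig" and a.target_id not in contig_kb:
            raise KeyError(f"anchor {a.marker_id}: unknown contig {a.target_id}")
        pos = marker_pos.get(a.marker_id)
        if pos is None:
            unplaced.append(a)
            continue
        lg_id, cm = pos
        grouped.setdefault((lg_id, a.target_kind, a.target_id), []).append(
            (a.marker_id, cm)
        )

    elements: list[IntegratedElement] = []
    warnings: list[str] = []
    for (lg_id, kind, target_id), markers in sorted(grouped.items()):
        markers = sorted(markers, key=lambda t: (t[1], t[0]))
        length_kb = contig_kb[target_id] if kind == "contig" else cfg.bac_insert_kb
        span = markers[-1][1] - markers[0][1]
        if span > INTRA_LG_SPAN_WARN_CM:
            warnings.append(
                f"{target_id} on {lg_id}: anchor span {span:.1f} cM exceeds "
                f"{INTRA_LG_SPAN_WARN_CM:.0f} cM"
            )
        elements.append(
            IntegratedElement(
                lg_id, kind, target_id, markers, length_kb,
                orientable=len(markers) >= 2,
            )
        )

    lgs_of: dict[str, set[str]] = {}
    for e in elements:
        lgs_of.setdefault(e.element_id, set()).add(e.lg_id)
    for e in elements:
        e.conflict = e.element_kind == "contig" and len(lgs_of[e.element_id]) >= 2
    return IntegratedMap(elements, unplaced, warnings)


def physical_coverage(
    imap: IntegratedMap, cfg: PipelineConfig, genome_mb: float | None = None
) -> CoverageReport:
    """Physical length accounting.

    Per-LG sums count every attachment (redundant); the non-redundant totals
    count each distinct contig or BAC once.  Mb values are rounded to 2
    decimals at this reporting boundary only.
    """
    per_lg_kb: dict[str, float] = {}
    for e in imap.elements:
        per_lg_kb[e.lg_id] = per_lg_kb.get(e.lg_id, 0.0) + e.length_kb

    seen: dict[str, IntegratedElement] = {}
    for e in imap.elements:
        seen.setdefault(e.element_id, e)
    contig_kb = sum(e.length_kb for e in seen.values() if e.element_kind == "contig")
    bac_kb = sum(e.length_kb for e in seen.values() if e.element_kind == "single_bac")
    n_contigs = sum(1 for e in seen.values() if e.element_kind == "contig")
    n_bacs = sum(1 for e in seen.values() if e.element_kind == "single_bac")

    total_red_kb = sum(per_lg_kb.values())
    total_nonred_kb = contig_kb + bac_kb
    genome = genome_mb if genome_mb is not None else cfg.genome_size_mb
    return CoverageReport(
        per_lg_mb={lg: round(kb / 1000.0, 2) for lg, kb in sorted(per_lg_kb.items())},
        total_redundant_mb=round(total_red_kb / 1000.0, 2),
        total_nonredundant_mb=round(total_nonred_kb / 1000.0, 2),
        contig_mb_nonredundant=round(contig_kb / 1000.0, 2),
        single_bac_mb=round(bac_kb / 1000.0, 2),
        n_contigs_nonredundant=n_contigs,
        n_single_bacs=n_bacs,
        genome_fraction=round(total_nonred_kb / 1000.0 / genome, 4),
    )


def detect_conflicts(imap: IntegratedMap) -> tuple[list[str], int]:
    """Contigs anchored on two or more linkage groups, plus the error-rate
    estimate: 100 * conflicting / anchored contigs, rounded to the nearest
    integer percent."""
    contig_lgs: dict[str, set[str]] = {}
    for e in imap.elements:
        if e.element_kind == "contig":
            contig_lgs.setdefault(e.element_id, set()).add(e.lg_id)
    conflicting = sorted(c for c, lgs in contig_lgs.items() if len(lgs) >= 2)
    n_anchored = len(contig_lgs)
    rate = int(round(100.0 * len(conflicting) / n_anchored)) if n_anchored else 0
    return conflicting, rate


def duplicated_pairs_from_map(gmap: GeneticMap) -> list[tuple[str, str | None, str | None]]:
    """(base_id, lg_a, lg_b) for every ``-1``/``-2`` suffixed marker pair;
    an unmapped locus yields None for its LG."""
    pos = gmap.marker_to_lg()
    bases: dict[str, dict[str, str | None]] = {}
    ids = set(pos)
    for g in gmap.groups:
        ids.update(g.marker_ids)
    ids.update(gmap.excluded)
    for mid in ids:
        if mid.endswith("-1") or mid.endswith("-2"):
            base, suffix = mid[:-2], mid[-1]
            lg = pos[mid][0] if mid in pos else None
            bases.setdefault(base, {})[suffix] = lg
    out = []
    for base in sorted(bases):
        loci = bases[base]
        if set(loci) == {"1", "2"}:
            out.append((base, loci["1"], loci["2"]))
    return out


def classify_duplicated_markers(
    pairs: list[tuple[str, str | None, str | None]],
    homology: dict[str, str] | None = None,
) -> tuple[list[DuplicatedMarkerPair], list[str], dict[str, int]]:
    """Classify duplicated-marker pairs as WGD-consistent (two distinct LGs)
    or intra-LG (both loci on one LG, suggesting segmental duplication).

    When a homology assignment maps both LGs of a distinct-LG pair to the
    same reference chromosome, that chromosome is annotated.  Pairs with an
    unmapped locus are returned as unclassifiable.  Returns
    (classified, unclassifiable base ids, counts).
    """
    classified: list[DuplicatedMarkerPair] = []
    unclassifiable: list[str] = []
    for base, lg_a, lg_b in pairs:
        if lg_a is None or lg_b is None:
            unclassifiable.append(base)
            continue
        if lg_a == lg_b:
            classified.append(DuplicatedMarkerPair(base, lg_a, lg_b, "intra_lg",
                                                   (homology or {}).get(lg_a)))
        else:
            chrom = None
            if homology and homology.get(lg_a) is not None and homology.get(lg_a) == homology.get(lg_b):
                chrom = homology[lg_a]
            classified.append(DuplicatedMarkerPair(base, lg_a, lg_b, "wgd_consistent", chrom))
    counts = {
        "wgd_consistent": sum(1 for p in classified if p.classification == "wgd_consistent"),
        "intra_lg": sum(1 for p in classified if p.classification == "intra_lg"),
        "unclassifiable": len(unclassifiable),
    }
    return classified, unclassifiable, counts


def integrated_map_table(imap: IntegratedMap) -> pd.DataFrame:
    """Flat TSV-ready view: one row per (element, anchoring marker)."""
    rows = []
    for e in sorted(imap.elements, key=lambda e: (e.lg_id, e.position_cM, e.element_id)):
        for marker_id, cm in e.markers:
            rows.append(
                {
                    "lg_id": e.lg_id,
                    "position_cM": round(cm, 3),
                    "marker_id": marker_id,
                    "element_kind": e.element_kind,
                    "element_id": e.element_id,
                    "length_kb": round(e.length_kb, 3),
                    "orientation": e.orientation,
                    "orientable": e.orientable,
                    "conflict": e.conflict,
                }
            )
    return pd.DataFrame(rows)
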