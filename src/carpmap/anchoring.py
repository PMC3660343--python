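"""Anchor genetic markers to BACs and physical-map contigs through BES.

A marker is anchored by aligning its sequence against the BAC-end sequence
set.  Alignments come either from real BLASTn tabular output (drop-in) or
from the built-in seed-and-extend aligner below, which exists so the whole
pipeline runs without an external binary.  Accepted hits must span at least
150 bp for microsatellites (100 bp for SNPs) with identity strictly above
95%; the hit's BES resolves through its clone to a physical-map contig or a
singleton BAC.

The module also mines contig-anchored microsatellite candidate loci: perfect
di-/tri-/tetranucleotide repeats of total length >= 12 bp with >= 50 bp of
flank on both sides, taken from contigs longer than 1 Mb, at most two loci
per contig.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dataio import (
    SINGLETON,
    AlignmentHit,
    PhysicalMap,
    PipelineConfig,
    clone_of_bes,
)

__all__ = [
    "MarkerAnchor",
    "naive_align",
    "align_markers",
    "filter_anchor_hits",
    "hit_reject_reason",
    "resolve_targets",
    "find_ssr_motifs",
    "select_candidate_loci",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MarkerAnchor:
    marker_id: str
    bes_id: str
    clone_id: str
    target_kind: str  # "contig" | "single_bac"
    target_id: str
    accepted: bool
    reject_reason: str = "none"  # below_length | below_identity | above_evalue | none

    def __post_init__(self) -> None:
        if self.accepted and self.reject_reason != "none":
            raise ValueError("accepted anchor cannot carry a reject reason")


# ---------------------------------------------------------------------------
# naive aligner
# ---------------------------------------------------------------------------


def _best_ungapped_segment(q: str, s: str, diag: int) -> tuple[int, int, int] | None:
    """Best-scoring ungapped segment on one diagonal (match +1, mismatch -2).

    Returns (q_start, q_end, matches) 0-based half-open on the query, or None.
    Maximum-scoring subarray over the full overlap of query and subject.
    """
    q0 = max(0, -diag)
    q1 = min(len(q), len(s) - diag)
    if q1 <= q0:
        return None
    best = (0.0, q0, q0)  # score, start, end
    score = 0.0
    start = q0
    for k in range(q0, q1):
        if score <= 0:
            score, start = 0.0, k
        score += 1.0 if q[k] == s[k + diag] else -2.0
        if score > best[0]:
            best = (score, start, k + 1)
    if best[0] <= 0:
        return None
    qs, qe = best[1], best[2]
    m = sum(1 for k in range(qs, qe) if q[k] == s[k + diag])
    return qs, qe, m


def _build_seed_index(bes_set: dict[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    """k-mer -> [(subject_id, position)] over the whole BES set."""
    index: dict[str, list[tuple[str, int]]] = {}
    for subject_id in sorted(bes_set):
        s = bes_set[subject_id].upper()
        for pos in range(len(s) - k + 1):
            index.setdefault(s[pos : pos + k], []).append((subject_id, pos))
    return index


def _align_one(
    query_id: str,
    query_seq: str,
    index: dict[str, list[tuple[str, int]]],
    bes_set: dict[str, str],
    k: int,
) -> list[AlignmentHit]:
    q = query_seq.upper()
    if not q:
        raise ValueError(f"query {query_id}: empty sequence")
    if len(q) < k:
        return []
    hits: list[AlignmentHit] = []
    for strand_q, strand in ((q, "+"), (_revcomp(q), "-")):
        diags: dict[str, set[int]] = {}
        for qpos in range(len(strand_q) - k + 1):
            for subject_id, spos in index.get(strand_q[qpos : qpos + k], ()):
                diags.setdefault(subject_id, set()).add(spos - qpos)
        for subject_id in sorted(diags):
            s = bes_set[subject_id].upper()
            best: tuple[int, int, int, int] | None = None  # qs, qe, matches, diag
            for diag in sorted(diags[subject_id]):
                seg = _best_ungapped_segment(strand_q, s, diag)
                if seg is None:
                    continue
                qs, qe, m = seg
                if best is None or (m, qe - qs) > (best[2], best[1] - best[0]):
                    best = (qs, qe, m, diag)
            if best is None:
                continue
            qs, qe, m, diag = best
            length = qe - qs
            ss, se = qs + diag, qe + diag  # 0-based half-open on subject
            if strand == "+":
                qstart, qend = qs + 1, qe
                sstart, send = ss + 1, se
            else:
                # coordinates on the forward query, minus-strand subject
                qstart, qend = len(q) - qe + 1, len(q) - qs
                sstart, send = se, ss + 1
            hits.append(
                AlignmentHit(
                    query_id,
                    subject_id,
                    round(100.0 * m / length, 2),
                    length,
                    length - m,
                    0,
                    qstart,
                    qend,
                    sstart,
                    send,
                    0.0,
                    2.0 * m,
                )
            )
    hits.sort(key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
    return hits


def naive_align(
    query_id: str,
    query_seq: str,
    bes_set: dict[str, str],
    k: int = 21,
) -> list[AlignmentHit]:
    """Exact-seed (k=21) and ungapped-extension alignment of one marker
    against every BES; reports the best segment per subject and strand in
    BLAST tabular convention.  Deterministic; e-value is reported as 0 for
    seeded hits (identity and length are the deciding statistics here).
    """
    return _align_one(query_id, query_seq, _build_seed_index(bes_set, k), bes_set, k)


def align_markers(
    marker_seqs: dict[str, str], bes_set: dict[str, str], k: int = 21
) -> list[AlignmentHit]:
    """Naive-align every marker sequence against the BES set (the seed
    index over the BES set is built once and shared)."""
    index = _build_seed_index(bes_set, k)
    out: list[AlignmentHit] = []
    for marker_id in sorted(marker_seqs):
        out.extend(_align_one(marker_id, marker_seqs[marker_id], index, bes_set, k))
    return out


# ---------------------------------------------------------------------------
# acceptance thresholds
# ---------------------------------------------------------------------------


def hit_reject_reason(hit: AlignmentHit, marker_type: str, cfg: PipelineConfig) -> str:
    """Why a hit fails the anchoring thresholds; "none" when it passes.

    Boundary semantics: length thresholds are inclusive (>= 150 / >= 100 bp),
    identity is strict (> 95%).
    """
    min_len = cfg.ssr_min_align_bp if marker_type == "SSR" else cfg.snp_min_align_bp
    if hit.align_len < min_len:
        return "below_length"
    if not hit.identity_pct > cfg.min_identity_pct:
        return "below_identity"
    if hit.evalue > cfg.evalue_cutoff:
        return "above_evalue"
    return "none"


def filter_anchor_hits(
    hits: list[AlignmentHit], marker_type: str, cfg: PipelineConfig
) -> list[AlignmentHit]:
    """Hits passing the thresholds, best first (bitscore desc, evalue asc,
    subject id asc)."""
    accepted = [h for h in hits if hit_reject_reason(h, marker_type, cfg) == "none"]
    accepted.sort(key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
    return accepted


# ---------------------------------------------------------------------------
# target resolution
# ---------------------------------------------------------------------------


def resolve_targets(
    hits_by_marker: dict[str, list[AlignmentHit]],
    marker_types: dict[str, str],
    pm: PhysicalMap,
    cfg: PipelineConfig,
) -> tuple[list[MarkerAnchor], list[dict]]:
    """Resolve each marker's best accepted hit to a contig or single BAC.

    Markers whose two best hits score identically on two different contigs
    are assigned to neither (conservative; reported as an issue).  A marker
    with accepted hits on two contigs keeps the best and the conflict is
    reported.  BES whose clone is absent from the physical map are reported
    as unresolved.  Returns (anchors, issues).
    """
    anchors: list[MarkerAnchor] = []
    issues: list[dict] = []
    for marker_id in sorted(hits_by_marker):
        mtype = marker_types.get(marker_id, "SSR")
        all_hits = hits_by_marker[marker_id]
        accepted = filter_anchor_hits(all_hits, mtype, cfg)
        if not accepted:
            for h in all_hits[:1]:
                anchors.append(
                    MarkerAnchor(
                        marker_id,
                        h.subject_id,
                        clone_of_bes(h.subject_id),
                        "none",
                        "",
                        False,
                        hit_reject_reason(h, mtype, cfg),
                    )
                )
            continue

        resolved: list[tuple[AlignmentHit, str, str]] = []  # hit, kind, target
        for h in accepted:
            clone = clone_of_bes(h.subject_id)
            target = pm.contig_of_clone(clone)
            if target is None:
                issues.append(
                    {"marker_id": marker_id, "bes_id": h.subject_id,
                     "issue": "unresolved_clone"}
                )
                continue
            kind = "single_bac" if target == SINGLETON else "contig"
            resolved.append((h, kind, clone if kind == "single_bac" else target))
        if not resolved:
            continue

        best = resolved[0]
        # equal-best hits on two different contigs -> assign neither
        ties = [
            r for r in resolved
            if (r[0].bitscore, r[0].evalue) == (best[0].bitscore, best[0].evalue)
            and r[2] != best[2]
        ]
        if ties:
            issues.append(
                {"marker_id": marker_id, "bes_id": best[0].subject_id,
                 "issue": "ambiguous_equal_best",
                 "targets": sorted({best[2]} | {r[2] for r in ties})}
            )
            continue
        others = sorted({r[2] for r in resolved if r[2] != best[2]})
        if others:
            issues.append(
                {"marker_id": marker_id, "bes_id": best[0].subject_id,
                 "issue": "secondary_targets", "targets": others}
            )
        h, kind, target = best
        anchors.append(
            MarkerAnchor(marker_id, h.subject_id, clone_of_bes(h.subject_id),
                         kind, target, True)
        )
    return anchors, issues


# ---------------------------------------------------------------------------
# SSR candidate loci
# ---------------------------------------------------------------------------

def find_ssr_motifs(seq: str, min_total_len: int = 12) -> list[tuple[int, int, str]]:
    """Maximal perfect repeats of 2-4 bp units, total length >= min_total_len.

    Homopolymer-equivalent units (e.g. AA, AAA) are excluded.  Returns
    (start, end, unit) 0-based half-open, longest first, overlaps removed.
    """
    seq = seq.upper()
    found: list[tuple[int, int, str]] = []
    for unit_len in (2, 3, 4):
        i = 0
        while i + 2 * unit_len <= len(seq):
            unit = seq[i : i + unit_len]
            if len(set(unit)) == 1 or "N" in unit:
                i += 1
                continue
            j = i + unit_len
            while seq[j : j + unit_len] == unit:
                j += unit_len
            total = j - i
            if total >= max(min_total_len, 2 * unit_len) and total // unit_len >= 3:
                found.append((i, j, unit))
                i = j
            else:
                i += 1
    found.sort(key=lambda t: (-(t[1] - t[0]), t[0]))
    kept: list[tuple[int, int, str]] = []
    for cand in found:
        if all(cand[1] <= k[0] or cand[0] >= k[1] for k in kept):
            kept.append(cand)
    kept.sort(key=lambda t: t[0])
    return kept


def select_candidate_loci(
    pm: PhysicalMap,
    bes_set: dict[str, str],
    cfg: PipelineConfig,
    min_flank_bp: int = 50,
    max_loci_per_contig: int = 2,
) -> "pd.DataFrame":
    """Candidate contig-anchored SSR loci for marker development.

    Contigs longer than 1 Mb (cb_length * kb_per_cb > 1000 kb) are ranked by
    size descending; within each, BES-borne perfect repeats with >= 50 bp of
    flank on both sides are collected and up to two loci (longest repeats
    first) are emitted per contig.
    """
    import pandas as pd

    rows: list[dict] = []
    ranked = sorted(pm.contigs, key=lambda c: (-c.cb_length, c.contig_id))
    for contig in ranked:
        size_kb = contig.cb_length * cfg.kb_per_cb
        if size_kb <= 1000.0:
            continue
        candidates: list[dict] = []
        for clone in sorted(contig.clone_ids):
            for end in ("f", "r"):
                bes_id = f"{clone}.{end}"
                seq = bes_set.get(bes_id)
                if not seq:
                    continue
                for start, stop, unit in find_ssr_motifs(seq):
                    left, right = start, len(seq) - stop
                    if left >= min_flank_bp and right >= min_flank_bp:
                        candidates.append(
                            {
                                "contig_id": contig.contig_id,
                                "contig_kb": round(size_kb, 1),
                                "bes_id": bes_id,
                                "unit": unit,
                                "start": start,
                                "end": stop,
                                "repeat_len": stop - start,
                                "flank_left": left,
                                "flank_right": right,
                            }
                        )
        candidates.sort(key=lambda r: (-r["repeat_len"], r["bes_id"], r["start"]))
        rows.extend(candidates[:max_loci_per_contig])
    return pd.DataFrame(rows)
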