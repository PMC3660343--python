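"""Synthetic data with the statistical structure the pipeline assumes.

Emulates the mapping design end to end: a single outbred F1 full-sib (CP)
family of 107 genotyped offspring segregating markers of all five CP types;
an FPC-style physical map whose contigs carry BAC-end sequences (BES) with
marker sequences embedded verbatim; and a diploid reference genome in which
every chromosome is homologous to exactly two linkage groups (the 2:1
pattern left by a lineage-specific whole-genome duplication), with optional
per-LG segmental loss.

Crossovers are simulated per adjacent marker interval with recombination
probability equal to the inverse Kosambi of the true cM gap (no explicit
interference model), which makes Kosambi-based map estimation consistent
with the generator's truth.  Segregation distortion is injected by biasing
the heterozygous parent's transmitted allele to 0.75.  A configurable
fraction of contigs is made chimeric (carrying a BES from a second linkage
group) to exercise conflict detection.

Everything is deterministic given the seed, and all outputs are written in
the dataio formats plus a ``truth/`` directory of TSVs for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import (
    MISSING,
    PARENT_ALLELES,
    AlignmentHit,
    GenotypeTable,
    MarkerRecord,
    PhysicalContig,
    PhysicalMap,
    genotype_alphabet,
    offspring_code,
    write_blast_tab,
    write_fasta,
    write_genotypes,
    write_physical_map,
)
from .linkage import inverse_kosambi

__all__ = [
    "SimConfig",
    "TrueGenome",
    "simulate_true_genome",
    "simulate_cp_family",
    "simulate_physical_and_bes",
    "simulate_reference_placements",
    "write_sim_dataset",
]

_DEFAULT_MIX = {
    "lmxll": 0.25,
    "nnxnp": 0.25,
    "hkxhk": 0.20,
    "efxeg": 0.15,
    "abxcd": 0.15,
}


@dataclass
class SimConfig:
    """Generator knobs; defaults mirror the real map's per-LG scale
    (~80 cM groups, ~20 markers each, 107 genotyped offspring)."""

    n_lgs: int = 10
    mean_lg_cM: float = 80.0
    markers_per_lg: int = 20
    n_offspring: int = 107
    segtype_mix: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MIX))
    missing_rate: float = 0.02
    distortion_frac: float = 0.05
    genotyping_error_rate: float = 0.0  # off by default; exposed as a knob
    n_contigs: int = 60
    cb_length_range: tuple[int, int] = (300, 2200)
    clones_per_contig: int = 3
    n_singleton_clones: int = 10
    n_singleton_bac_markers: int = 4
    chimeric_fraction: float = 0.0
    dup_marker_count: int = 4
    dup_intra_fraction: float = 5.0 / 13.0  # same-LG share seen among duplicated loci
    marker_seq_len: int = 220
    bes_len: int = 700
    embedding_error_rate: float = 0.0  # substitutions into embedded marker copies
    loss_fractions: dict[str, float] = field(default_factory=dict)  # lg_id -> fraction
    ref_bp_per_cM: int = 100_000
    ref_jitter_bp: int = 40_000
    decoy_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.segtype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("segtype_mix proportions must sum to 1")
        for name in ("n_lgs", "markers_per_lg", "n_offspring", "n_contigs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for f in self.loss_fractions.values():
            if not 0.0 <= f < 1.0:
                raise ValueError("loss fractions must lie in [0, 1)")


@dataclass
class TrueMarker:
    marker_id: str
    position_cM: float
    segregation_type: str


@dataclass
class TrueLG:
    lg_id: str
    length_cM: float
    markers: list[TrueMarker]


@dataclass
class ContigPlacement:
    contig_id: str
    lg_id: str
    cM_anchor: float
    cb_length: int
    anchor_marker_ids: list[str]


@dataclass
class TrueGenome:
    linkage_groups: list[TrueLG]
    contig_placements: list[ContigPlacement]
    reference_homology: dict[str, str]  # lg_id -> chromosome
    loss_intervals: dict[str, float]  # lg_id -> lost fraction of its chromosome
    duplicated_marker_pairs: list[tuple[str, str, str]]  # (base_id, lg_a, lg_b)

    def lg(self, lg_id: str) -> TrueLG:
        for g in self.linkage_groups:
            if g.lg_id == lg_id:
                return g
        raise KeyError(lg_id)

    def all_markers(self) -> list[tuple[str, TrueMarker]]:
        return [(g.lg_id, m) for g in self.linkage_groups for m in g.markers]


def simulate_true_genome(cfg: SimConfig) -> TrueGenome:
    """Draw marker positions, segregation types, duplicated-marker pairs,
    contig placements and the 2:1 LG-to-chromosome homology structure."""
    rng = np.random.default_rng(cfg.seed)
    types = list(cfg.segtype_mix)
    probs = np.array([cfg.segtype_mix[t] for t in types])

    lgs: list[TrueLG] = []
    mean_gap = cfg.mean_lg_cM / max(cfg.markers_per_lg - 1, 1)
    for g in range(cfg.n_lgs):
        lg_id = f"TLG{g + 1}"
        gaps = rng.uniform(0.5 * mean_gap, 1.5 * mean_gap, size=max(cfg.markers_per_lg - 1, 0))
        positions = np.concatenate(([0.0], np.cumsum(gaps)))
        markers = [
            TrueMarker(
                f"M{g + 1:02d}_{k + 1:03d}",
                float(positions[k]),
                types[rng.choice(len(types), p=probs)],
            )
            for k in range(cfg.markers_per_lg)
        ]
        lgs.append(TrueLG(lg_id, float(positions[-1]), markers))

    # every reference chromosome hosts exactly two LGs (WGD homeologs);
    # an odd trailing LG shares the last chromosome with its predecessor
    homology: dict[str, str] = {}
    for g in range(cfg.n_lgs):
        idx = g if (g < cfg.n_lgs - 1 or cfg.n_lgs % 2 == 0) else g - 1
        homology[lgs[g].lg_id] = f"chr{idx // 2 + 1}"

    # duplicated loci: a pair of markers sharing a base id, inserted either
    # on two homeologous LGs (WGD-consistent) or twice on one LG (segmental)
    dup_pairs: list[tuple[str, str, str]] = []
    n_intra = int(round(cfg.dup_marker_count * cfg.dup_intra_fraction))
    for k in range(cfg.dup_marker_count):
        base = f"DUP{k + 1:02d}"
        if k < cfg.dup_marker_count - n_intra and cfg.n_lgs >= 2:
            pair_start = 2 * int(rng.integers(0, cfg.n_lgs // 2))
            lg_a, lg_b = lgs[pair_start].lg_id, lgs[pair_start + 1].lg_id
        else:
            lg_a = lg_b = lgs[int(rng.integers(0, cfg.n_lgs))].lg_id
        for suffix, lg_id in (("-1", lg_a), ("-2", lg_b)):
            target = next(g for g in lgs if g.lg_id == lg_id)
            pos = float(rng.uniform(0.0, target.length_cM))
            seg = types[rng.choice(len(types), p=probs)]
            target.markers.append(TrueMarker(base + suffix, pos, seg))
            target.markers.sort(key=lambda m: (m.position_cM, m.marker_id))
            # keep the first marker at 0 cM
            shift = target.markers[0].position_cM
            if shift:
                for m in target.markers:
                    m.position_cM -= shift
                target.length_cM = target.markers[-1].position_cM
        dup_pairs.append((base, lg_a, lg_b))

    # contigs: placed on LGs round-robin, each anchored by 1-2 distinct
    # markers not reused across contigs (duplicated loci are left free)
    placements: list[ContigPlacement] = []
    free: dict[str, list[str]] = {
        g.lg_id: [m.marker_id for m in g.markers if not m.marker_id.startswith("DUP")]
        for g in lgs
    }
    pos_of = {m.marker_id: m.position_cM for g in lgs for m in g.markers}
    for c in range(cfg.n_contigs):
        lg = lgs[c % cfg.n_lgs]
        pool = free[lg.lg_id]
        if not pool:
            continue
        picks = [pool.pop(int(rng.integers(0, len(pool))))]
        if len(pool) and rng.random() < 0.5:
            # a second anchor must sit within the contig's physical reach:
            # take the nearest remaining marker if it is close enough
            cm0 = pos_of[picks[0]]
            nearest = min(range(len(pool)), key=lambda k: abs(pos_of[pool[k]] - cm0))
            if abs(pos_of[pool[nearest]] - cm0) <= 5.0:
                picks.append(pool.pop(nearest))
        cb = int(rng.integers(cfg.cb_length_range[0], cfg.cb_length_range[1] + 1))
        cm = float(np.mean([pos_of[p] for p in picks]))
        placements.append(ContigPlacement(f"ctg{c + 1:04d}", lg.lg_id, cm, cb, picks))

    loss = {g.lg_id: float(cfg.loss_fractions.get(g.lg_id, 0.0)) for g in lgs}
    return TrueGenome(lgs, placements, homology, loss, dup_pairs)


# ---------------------------------------------------------------------------
# family genotypes
# ---------------------------------------------------------------------------

# transmitted-allele index -> genotype code, per type: CODE_TABLE[t][mi][fi]
_CODE_TABLE = {
    t: [
        [offspring_code(PARENT_ALLELES[t][0][mi], PARENT_ALLELES[t][1][fi]) for fi in (0, 1)]
        for mi in (0, 1)
    ]
    for t in PARENT_ALLELES
}


def _gamete_alleles(rng: np.random.Generator, r_gaps: np.ndarray, n_off: int) -> np.ndarray:
    """Haplotype state (0/1) per offspring per marker under interval
    recombination probabilities ``r_gaps``; shape (n_off, n_markers)."""
    n_mark = len(r_gaps) + 1
    switches = rng.random((n_off, n_mark)) < np.concatenate(([0.5], r_gaps))
    return np.cumsum(switches, axis=1) % 2


def simulate_cp_family(genome: TrueGenome, cfg: SimConfig) -> GenotypeTable:
    """Simulate offspring genotype codes for every marker in the genome.

    Each parent's linkage phase (which allele rides which haplotype) is drawn
    uniformly per marker; gametes recombine between adjacent markers with the
    inverse-Kosambi probability of the cM gap.  Missing codes, distorted
    markers and (optionally) genotyping errors are injected afterwards.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n_off = cfg.n_offspring
    records: list[MarkerRecord] = []

    # choose distorted markers up front
    all_ids = [m.marker_id for _, m in genome.all_markers()]
    n_dist = int(round(cfg.distortion_frac * len(all_ids)))
    distorted = set(rng.choice(all_ids, size=n_dist, replace=False)) if n_dist else set()

    for lg in genome.linkage_groups:
        markers = lg.markers
        gaps = np.diff([m.position_cM for m in markers])
        r_gaps = np.array([inverse_kosambi(g) for g in gaps])
        # per-parent phase assignment: hap0 carries allele s[m] at marker m
        s_m = rng.integers(0, 2, size=len(markers))
        s_f = rng.integers(0, 2, size=len(markers))
        hap_m = _gamete_alleles(rng, r_gaps, n_off)
        hap_f = _gamete_alleles(rng, r_gaps, n_off)
        mi = s_m[None, :] ^ hap_m  # maternal transmitted allele index
        fi = s_f[None, :] ^ hap_f
        for k, tm in enumerate(markers):
            t = tm.segregation_type
            mother_het = PARENT_ALLELES[t][0][0] != PARENT_ALLELES[t][0][1]
            m_idx = mi[:, k].copy()
            f_idx = fi[:, k].copy()
            if tm.marker_id in distorted:
                # the heterozygous parent transmits allele 0 with probability 0.75
                biased = (rng.random(n_off) >= 0.75).astype(int)
                if mother_het:
                    m_idx = biased
                else:
                    f_idx = biased
            table = _CODE_TABLE[t]
            codes = np.array([[table[0][0], table[0][1]], [table[1][0], table[1][1]]])
            out = codes[m_idx, f_idx]
            if cfg.genotyping_error_rate > 0:
                alpha = genotype_alphabet(t)
                err = rng.random(n_off) < cfg.genotyping_error_rate
                for idx in np.nonzero(err)[0]:
                    choices = [c for c in alpha if c != out[idx]]
                    out[idx] = choices[int(rng.integers(0, len(choices)))]
            if cfg.missing_rate > 0:
                miss = rng.random(n_off) < cfg.missing_rate
                out = np.where(miss, MISSING, out)
            records.append(
                MarkerRecord(
                    tm.marker_id,
                    t,
                    tuple(out.tolist()),
                    marker_type="SNP" if tm.marker_id.startswith("SNP") else "SSR",
                )
            )
    return GenotypeTable("SIMFAM", n_off, records)


# ---------------------------------------------------------------------------
# physical map, BES and marker sequences
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_SSR_UNITS = ("AC", "AG", "AT", "CT", "ACT", "AAG", "ACAG")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _marker_sequence(rng: np.random.Generator, length: int) -> str:
    """Random sequence with a perfect SSR motif inside (markers here are
    microsatellites, so their amplicons carry the repeat)."""
    unit = _SSR_UNITS[int(rng.integers(0, len(_SSR_UNITS)))]
    reps = int(rng.integers(8, 13))
    motif = unit * reps
    flank = length - len(motif)
    left = flank // 2
    return _random_seq(rng, left) + motif + _random_seq(rng, flank - left)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in np.nonzero(rng.random(len(chars)) < rate)[0]:
        chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
    return "".join(chars)


def simulate_physical_and_bes(
    genome: TrueGenome, cfg: SimConfig
) -> tuple[PhysicalMap, dict[str, str], dict[str, str], pd.DataFrame]:
    """Build the physical map, the BES set and marker sequences.

    Every contig's anchor markers are embedded verbatim (or with the
    configured substitution rate) into one of its BES.  A ``chimeric_fraction``
    share of contigs additionally receives a BES carrying a marker from a
    different linkage group.  Some singleton clones carry markers too.

    Returns (physical map, bes sequences, marker sequences, truth table)
    where the truth table has one row per embedded marker:
    marker_id, bes_id, target_kind, target_id, lg_id, chimeric_extra.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    marker_seqs = {
        m.marker_id: _marker_sequence(rng, cfg.marker_seq_len)
        for _, m in genome.all_markers()
    }

    # pool of markers not anchoring any contig, for chimeric/singleton use
    anchored = {mid for p in genome.contig_placements for mid in p.anchor_marker_ids}
    spare: dict[str, list[str]] = {}
    for lg_id, m in genome.all_markers():
        if m.marker_id not in anchored and not m.marker_id.startswith("DUP"):
            spare.setdefault(lg_id, []).append(m.marker_id)

    n_chim = int(round(cfg.chimeric_fraction * len(genome.contig_placements)))
    chim_idx = set(
        rng.choice(len(genome.contig_placements), size=n_chim, replace=False).tolist()
    ) if n_chim else set()

    contigs: list[PhysicalContig] = []
    bes: dict[str, str] = {}
    truth_rows: list[dict] = []

    def embed(marker_id: str, bes_id: str) -> str:
        mseq = _mutate(rng, marker_seqs[marker_id], cfg.embedding_error_rate)
        pad = cfg.bes_len - len(mseq)
        off = int(rng.integers(0, max(pad, 1)))
        return _random_seq(rng, off) + mseq + _random_seq(rng, pad - off)

    for idx, placement in enumerate(genome.contig_placements):
        clone_ids = [
            f"SIM{placement.contig_id[3:]}C{c + 1:02d}" for c in range(cfg.clones_per_contig)
        ]
        reads = [f"{cl}.{end}" for cl in clone_ids for end in ("f", "r")]
        carriers = reads[: len(placement.anchor_marker_ids)]
        for marker_id, bes_id in zip(placement.anchor_marker_ids, carriers):
            bes[bes_id] = embed(marker_id, bes_id)
            truth_rows.append(
                {
                    "marker_id": marker_id,
                    "bes_id": bes_id,
                    "target_kind": "contig",
                    "target_id": placement.contig_id,
                    "lg_id": placement.lg_id,
                    "chimeric_extra": False,
                }
            )
        extra_clones: list[str] = []
        if idx in chim_idx:
            # splice in a BES whose marker belongs to a different LG
            others = [lg for lg in spare if lg != placement.lg_id and spare[lg]]
            if others:
                other_lg = others[int(rng.integers(0, len(others)))]
                marker_id = spare[other_lg].pop(int(rng.integers(0, len(spare[other_lg]))))
                chim_clone = f"SIM{placement.contig_id[3:]}X01"
                chim_read = f"{chim_clone}.f"
                bes[chim_read] = embed(marker_id, chim_read)
                extra_clones.append(chim_clone)
                truth_rows.append(
                    {
                        "marker_id": marker_id,
                        "bes_id": chim_read,
                        "target_kind": "contig",
                        "target_id": placement.contig_id,
                        "lg_id": other_lg,
                        "chimeric_extra": True,
                    }
                )
        for read in reads[len(placement.anchor_marker_ids) :]:
            bes[read] = _random_seq(rng, cfg.bes_len)
        contigs.append(
            PhysicalContig(
                placement.contig_id,
                placement.cb_length,
                frozenset(clone_ids + extra_clones),
            )
        )

    singletons: list[str] = []
    spare_flat = [
        (lg, mid) for lg, mids in sorted(spare.items()) for mid in mids
    ]
    rng.shuffle(spare_flat)
    for s in range(cfg.n_singleton_clones):
        clone = f"SIMSGL{s + 1:03d}"
        singletons.append(clone)
        read = f"{clone}.f"
        if s < cfg.n_singleton_bac_markers and spare_flat:
            lg_id, marker_id = spare_flat.pop()
            bes[read] = embed(marker_id, read)
            truth_rows.append(
                {
                    "marker_id": marker_id,
                    "bes_id": read,
                    "target_kind": "single_bac",
                    "target_id": clone,
                    "lg_id": lg_id,
                    "chimeric_extra": False,
                }
            )
        else:
            bes[read] = _random_seq(rng, cfg.bes_len)
        bes[f"{clone}.r"] = _random_seq(rng, cfg.bes_len)

    pm = PhysicalMap(contigs, frozenset(singletons))
    truth = pd.DataFrame(truth_rows)
    return pm, bes, marker_seqs, truth


# ---------------------------------------------------------------------------
# reference placements
# ---------------------------------------------------------------------------


def chromosome_lengths(genome: TrueGenome, cfg: SimConfig) -> dict[str, int]:
    """bp length per reference chromosome: scale of the longer homeolog."""
    out: dict[str, int] = {}
    for lg_id, chrom in genome.reference_homology.items():
        lg_len = int(genome.lg(lg_id).length_cM * cfg.ref_bp_per_cM)
        out[chrom] = max(out.get(chrom, 0), lg_len)
    return out


def simulate_reference_placements(
    genome: TrueGenome,
    cfg: SimConfig,
    pm: PhysicalMap,
    anchor_truth: pd.DataFrame,
) -> tuple[list[AlignmentHit], pd.DataFrame]:
    """BLAST-style hits of every BES onto the reference genome.

    Each contig BES hits its LG's homologous chromosome at a bp position
    collinear with its cM location (anchor cM plus jitter), unless it falls
    inside the LG's segmental-loss interval.  True hits get e-values far
    below the cutoff; a ``decoy_rate`` share of BES get an extra off-target
    hit with an e-value above the cutoff.  Returns (hits, truth) with truth
    rows (bes_id, lg_id, chromosome, bp, lost).
    """
    rng = np.random.default_rng(cfg.seed + 3)
    chrom_len = chromosome_lengths(genome, cfg)
    contig_lg = {p.contig_id: p.lg_id for p in genome.contig_placements}
    contig_cm = {p.contig_id: p.cM_anchor for p in genome.contig_placements}
    chim_bes_lg = {
        r.bes_id: r.lg_id for r in anchor_truth.itertuples() if r.chimeric_extra
    }

    loss_start: dict[str, float] = {}
    for lg_id, frac in genome.loss_intervals.items():
        if frac > 0:
            clen = chrom_len[genome.reference_homology[lg_id]]
            loss_start[lg_id] = float(rng.uniform(0, (1 - frac) * clen))

    hits: list[AlignmentHit] = []
    truth_rows: list[dict] = []
    chroms = sorted(chrom_len)

    def add_hit(bes_id: str, chrom: str, bp: int, evalue: float, bitscore: float) -> None:
        length = int(rng.integers(250, 550))
        ident = float(rng.uniform(96.0, 100.0))
        minus = rng.random() < 0.5
        sstart, send = (bp + length, bp + 1) if minus else (bp + 1, bp + length)
        hits.append(
            AlignmentHit(
                bes_id, chrom, round(ident, 2), length, int(length * (100 - ident) / 100),
                0, 1, length, sstart, send, evalue, round(bitscore, 1),
            )
        )

    for contig in pm.contigs:
        lg_id_c = contig_lg.get(contig.contig_id)
        if lg_id_c is None:
            continue
        lg = genome.lg(lg_id_c)
        chrom_c = genome.reference_homology[lg_id_c]
        for clone in sorted(contig.clone_ids):
            for end in ("f", "r"):
                bes_id = f"{clone}.{end}"
                lg_id = chim_bes_lg.get(bes_id, lg_id_c)
                this_lg = genome.lg(lg_id)
                chrom = genome.reference_homology[lg_id]
                clen = chrom_len[chrom]
                cm = contig_cm[contig.contig_id] if lg_id == lg_id_c else float(
                    rng.uniform(0, this_lg.length_cM)
                )
                bp = cm / max(this_lg.length_cM, 1e-9) * clen
                # BES spread across the contig's physical span around its anchor
                span = contig.cb_length * 1428.0
                bp += float(rng.uniform(-span / 2, span / 2))
                bp = int(np.clip(bp + rng.normal(0, cfg.ref_jitter_bp), 0, clen - 600))
                frac = genome.loss_intervals.get(lg_id, 0.0)
                lost = False
                if frac > 0:
                    a = loss_start[lg_id]
                    lost = a <= bp < a + frac * chrom_len[chrom]
                if not lost:
                    evalue = 10.0 ** -float(rng.uniform(10, 60))
                    add_hit(bes_id, chrom, bp, evalue, rng.uniform(300, 900))
                if rng.random() < cfg.decoy_rate:
                    wrong = chroms[int(rng.integers(0, len(chroms)))]
                    add_hit(
                        bes_id, wrong, int(rng.uniform(0, chrom_len[wrong] - 600)),
                        10.0 ** -float(rng.uniform(1.0, 4.9)), rng.uniform(30, 60),
                    )
                truth_rows.append(
                    {"bes_id": bes_id, "lg_id": lg_id, "chromosome": chrom,
                     "cM": cm, "bp": bp, "lost": lost}
                )
    return hits, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# dataset writer
# ---------------------------------------------------------------------------


def write_sim_dataset(cfg: SimConfig, outdir: str | Path) -> TrueGenome:
    """Generate and write one complete synthetic dataset in the pipeline's
    input formats, plus ``truth/`` TSVs for evaluation."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)

    genome = simulate_true_genome(cfg)
    family = simulate_cp_family(genome, cfg)
    pm, bes, marker_seqs, anchor_truth = simulate_physical_and_bes(genome, cfg)
    ref_hits, ref_truth = simulate_reference_placements(genome, cfg, pm, anchor_truth)

    write_genotypes(family, out / "genotypes.txt")
    write_physical_map(pm, out / "physical_map.tsv")
    write_fasta(bes, out / "bes.fasta")
    write_fasta(marker_seqs, out / "markers.fasta")
    write_blast_tab(ref_hits, out / "reference_hits.tsv")
    chrom_len = chromosome_lengths(genome, cfg)
    pd.DataFrame(
        [{"chromosome": c, "length_bp": l} for c, l in sorted(chrom_len.items())]
    ).to_csv(out / "reference_chromosomes.tsv", sep="\t", index=False)

    anchor_truth.to_csv(truth_dir / "marker_anchors.tsv", sep="\t", index=False)
    ref_truth.to_csv(truth_dir / "bes_reference.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"marker_id": m.marker_id, "lg_id": lg_id, "position_cM": m.position_cM,
             "segregation_type": m.segregation_type}
            for lg_id, m in genome.all_markers()
        ]
    ).to_csv(truth_dir / "marker_map.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"contig_id": p.contig_id, "lg_id": p.lg_id, "cM_anchor": p.cM_anchor,
             "cb_length": p.cb_length,
             "chimeric": bool(
                 (
                     (anchor_truth["target_id"] == p.contig_id)
                     & anchor_truth["chimeric_extra"]
                 ).any()
             )
             if len(anchor_truth)
             else False}
            for p in genome.contig_placements
        ]
    ).to_csv(truth_dir / "contig_placements.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"lg_id": lg, "chromosome": c} for lg, c in sorted(genome.reference_homology.items())]
    ).to_csv(truth_dir / "lg_homology.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"base_id": b, "lg_a": a, "lg_b": bb} for b, a, bb in genome.duplicated_marker_pairs]
    ).to_csv(truth_dir / "duplicated_markers.tsv", sep="\t", index=False)
    return genome
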