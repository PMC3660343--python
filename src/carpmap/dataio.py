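"""File formats and shared records for the map-integration pipeline.

The pipeline touches five external formats:

* a CP-family genotype dialect (one marker per line, JoinMap-style
  segregation codes for a full-sib family of two outbred parents);
* a physical-map TSV (FPC-style contigs with consensus-band lengths plus
  singleton clones);
* FASTA for marker sequences and BAC-end sequences (BES);
* 12-column BLAST tabular alignments;
* a flat ``key = value`` configuration file.

Everything is read into plain dataclasses.  All coordinates are converted to
0-based half-open at the file boundary; BLAST's 1-based inclusive convention
exists only inside :class:`AlignmentHit`'s raw fields.

Note on the genotype dialect: original JoinMap input files for the real
dataset are not public, so the dialect here is a reconstruction of common
CP-format practice, defined bit-exactly by :func:`write_genotypes`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = "--"
SINGLETON = "SINGLETON"

#: Parental allele pairs (mother, father) for the five CP segregation types.
PARENT_ALLELES: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "lmxll": (("l", "m"), ("l", "l")),
    "nnxnp": (("n", "n"), ("n", "p")),
    "hkxhk": (("h", "k"), ("h", "k")),
    "efxeg": (("e", "f"), ("e", "g")),
    "abxcd": (("a", "b"), ("c", "d")),
}

SEG_TYPES = tuple(PARENT_ALLELES)

#: Mendelian expectations for the locus genotype-frequency chi-square test.
EXPECTED_RATIOS: dict[str, dict[str, float]] = {}


def offspring_code(maternal: str, paternal: str) -> str:
    """Canonical genotype code for one maternal and one paternal allele."""
    return "".join(sorted((maternal, paternal)))


def genotype_alphabet(segregation_type: str) -> tuple[str, ...]:
    """Sorted tuple of legal genotype codes for a segregation type."""
    try:
        mother, father = PARENT_ALLELES[segregation_type]
    except KeyError:
        raise ValueError(f"unknown segregation type {segregation_type!r}") from None
    codes = {offspring_code(m, f) for m in mother for f in father}
    return tuple(sorted(codes))


def _expected_ratios(segregation_type: str) -> dict[str, float]:
    mother, father = PARENT_ALLELES[segregation_type]
    counts: dict[str, float] = {}
    for m, f in itertools.product(mother, father):
        code = offspring_code(m, f)
        counts[code] = counts.get(code, 0.0) + 0.25
    return counts


for _t in SEG_TYPES:
    EXPECTED_RATIOS[_t] = _expected_ratios(_t)


class FormatError(ValueError):
    """Raised on malformed input, naming the offending line where possible."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Numeric constants for every pipeline stage.

    Defaults are the analysis conditions: linkage grouping at LOD 5.0 with a
    sweep to 15.0, maximum recombination fraction 0.4, Kosambi distances,
    alignment acceptance at >=150 bp (SSR) / >=100 bp (SNP) with identity
    strictly above 95%, a BLAST e-value cutoff of 1e-5, the physical-map
    conversion of 1.428 kb per consensus band and a 141 kb mean BAC insert.
    """

    lod_group_threshold: float = 5.0
    lod_sweep: tuple[float, ...] = tuple(float(x) for x in range(5, 16))
    max_rf: float = 0.4
    distortion_alpha: float = 0.01
    ssr_min_align_bp: int = 150
    snp_min_align_bp: int = 100
    min_identity_pct: float = 95.0
    evalue_cutoff: float = 1e-5
    kb_per_cb: float = 1.428
    bac_insert_kb: float = 141.0
    synteny_max_gap_bp: int = 1_000_000
    homology_min_fraction: float = 0.5
    genome_size_mb: float = 1700.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.max_rf < 0.5:
            raise ValueError("max_rf must lie in (0, 0.5)")
        if self.kb_per_cb <= 0:
            raise ValueError("kb_per_cb must be positive")
        for name in (
            "lod_group_threshold",
            "distortion_alpha",
            "ssr_min_align_bp",
            "snp_min_align_bp",
            "min_identity_pct",
            "evalue_cutoff",
            "bac_insert_kb",
            "synteny_max_gap_bp",
            "homology_min_fraction",
            "genome_size_mb",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        sweep = tuple(float(x) for x in self.lod_sweep)
        if any(b <= a for a, b in zip(sweep, sweep[1:])):
            raise ValueError("lod_sweep must be strictly increasing")
        object.__setattr__(self, "lod_sweep", sweep)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat ``key = value`` file; unknown keys are rejected."""
        values: dict[str, object] = {}
        fields = {f: t for f, t in cls.__annotations__.items()}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected key = value")
            key, _, value = (x.strip() for x in line.partition("="))
            if key not in fields:
                raise FormatError(f"{path}:{lineno}: unknown config key {key!r}")
            if key == "lod_sweep":
                values[key] = tuple(float(x) for x in value.split(","))
            elif key in ("ssr_min_align_bp", "snp_min_align_bp", "synteny_max_gap_bp", "rng_seed"):
                values[key] = int(value)
            else:
                values[key] = float(value)
        return cls(**values)  # type: ignore[arg-type]

    def to_file(self, path: str | Path) -> None:
        lines = []
        for name in self.__dataclass_fields__:
            value = getattr(self, name)
            if name == "lod_sweep":
                value = ",".join(f"{x:g}" for x in value)
            lines.append(f"{name} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# genotype records
# ---------------------------------------------------------------------------


@dataclass
class MarkerRecord:
    """One marker's genotypes across the mapping family.

    ``phase`` is a two-character string (mother, father) over ``{0,1,-}``:
    the haplotype assignment of each parent's first allele, ``-`` when
    unknown.  Duplicated loci amplified by one primer pair are two records
    whose ids share a base with ``-1``/``-2`` suffixes.
    """

    marker_id: str
    segregation_type: str
    genotype_codes: tuple[str, ...]
    marker_type: str = "SSR"
    phase: str = "--"
    sequence: str | None = None

    def __post_init__(self) -> None:
        alphabet = set(genotype_alphabet(self.segregation_type))
        for code in self.genotype_codes:
            if code != MISSING and code not in alphabet:
                raise FormatError(
                    f"marker {self.marker_id}: code {code!r} not legal for "
                    f"{self.segregation_type}"
                )
        if len(self.phase) != 2 or any(c not in "01-" for c in self.phase):
            raise FormatError(f"marker {self.marker_id}: bad phase {self.phase!r}")
        if self.marker_type not in ("SSR", "SNP"):
            raise FormatError(f"marker {self.marker_id}: bad marker_type {self.marker_type!r}")

    @property
    def n_missing(self) -> int:
        return sum(1 for c in self.genotype_codes if c == MISSING)


@dataclass
class GenotypeTable:
    family_name: str
    n_offspring: int
    markers: list[MarkerRecord]

    def __post_init__(self) -> None:
        if self.n_offspring <= 0:
            raise FormatError("n_offspring must be positive")
        seen: set[str] = set()
        for m in self.markers:
            if len(m.genotype_codes) != self.n_offspring:
                raise FormatError(
                    f"marker {m.marker_id}: {len(m.genotype_codes)} genotypes, "
                    f"expected {self.n_offspring}"
                )
            if m.marker_id in seen:
                raise FormatError(f"duplicate marker id {m.marker_id}")
            seen.add(m.marker_id)

    def marker(self, marker_id: str) -> MarkerRecord:
        for m in self.markers:
            if m.marker_id == marker_id:
                return m
        raise KeyError(marker_id)


def read_genotypes(path: str | Path) -> GenotypeTable:
    """Parse the CP genotype dialect.

    Header: ``name = <family>``, ``popt = CP``, ``nloc = <int>``,
    ``nind = <int>``; then one marker per line:
    ``id<TAB><(segtype)><TAB><phase><TAB>code1 code2 ... codeN``.
    """
    header: dict[str, str] = {}
    markers: list[MarkerRecord] = []
    n_ind: int | None = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith(";"):
            continue
        if "=" in line and len(header) < 4 and not markers:
            key, _, value = (x.strip() for x in line.partition("="))
            header[key] = value
            continue
        if n_ind is None:
            for want in ("name", "popt", "nloc", "nind"):
                if want not in header:
                    raise FormatError(f"{path}:{lineno}: missing header field {want!r}")
            if header["popt"] != "CP":
                raise FormatError(f"{path}: population type {header['popt']!r}, expected CP")
            n_ind = int(header["nind"])
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"{path}:{lineno}: expected 4 tab-separated fields")
        marker_id, segfield, phase, codes_field = parts
        if not (segfield.startswith("<") and segfield.endswith(">")):
            raise FormatError(f"{path}:{lineno}: segregation type must be <...>")
        segtype = segfield[1:-1]
        if segtype not in PARENT_ALLELES:
            raise FormatError(f"{path}:{lineno}: unknown segregation type {segtype!r}")
        codes = tuple(codes_field.split())
        if len(codes) != n_ind:
            raise FormatError(
                f"{path}:{lineno}: {len(codes)} genotype codes, expected {n_ind}"
            )
        marker_type = "SNP" if marker_id.upper().startswith("SNP") else "SSR"
        try:
            markers.append(
                MarkerRecord(marker_id, segtype, codes, marker_type=marker_type, phase=phase)
            )
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    if n_ind is None:
        raise FormatError(f"{path}: empty genotype file")
    if len(markers) != int(header["nloc"]):
        raise FormatError(
            f"{path}: nloc = {header['nloc']} but {len(markers)} marker lines"
        )
    return GenotypeTable(header["name"], n_ind, markers)


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    lines = [
        f"name = {table.family_name}",
        "popt = CP",
        f"nloc = {len(table.markers)}",
        f"nind = {table.n_offspring}",
    ]
    for m in table.markers:
        codes = " ".join(m.genotype_codes)
        lines.append(f"{m.marker_id}\t<{m.segregation_type}>\t{m.phase}\t{codes}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# physical map
# ---------------------------------------------------------------------------


@dataclass
class BESRecord:
    """A BAC-end sequence: one read (.f or .r) from one end of a clone."""

    bes_id: str
    sequence: str
    contig_id: str = SINGLETON

    def __post_init__(self) -> None:
        if not (self.bes_id.endswith(".f") or self.bes_id.endswith(".r")):
            raise FormatError(f"BES id {self.bes_id!r} must end in .f or .r")

    @property
    def clone_id(self) -> str:
        return self.bes_id[:-2]


def clone_of_bes(bes_id: str) -> str:
    if not (bes_id.endswith(".f") or bes_id.endswith(".r")):
        raise FormatError(f"BES id {bes_id!r} must end in .f or .r")
    return bes_id[:-2]


@dataclass
class PhysicalContig:
    contig_id: str
    cb_length: int
    clone_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.cb_length < 1:
            raise FormatError(f"contig {self.contig_id}: cb_length must be >= 1")
        if not self.clone_ids:
            raise FormatError(f"contig {self.contig_id}: no member clones")


@dataclass
class PhysicalMap:
    contigs: list[PhysicalContig]
    singleton_clones: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for c in self.contigs:
            for clone in c.clone_ids:
                if clone in seen:
                    raise FormatError(
                        f"clone {clone} in contigs {seen[clone]} and {c.contig_id}"
                    )
                seen[clone] = c.contig_id
        overlap = self.singleton_clones & set(seen)
        if overlap:
            raise FormatError(f"singleton clones also in contigs: {sorted(overlap)[:3]}")
        self._clone_to_contig = seen

    def contig_of_clone(self, clone_id: str) -> str | None:
        """Contig id for a clone, SINGLETON for singletons, None if unknown."""
        if clone_id in self._clone_to_contig:
            return self._clone_to_contig[clone_id]
        if clone_id in self.singleton_clones:
            return SINGLETON
        return None

    def contig(self, contig_id: str) -> PhysicalContig:
        for c in self.contigs:
            if c.contig_id == contig_id:
                return c
        raise KeyError(contig_id)


def read_physical_map(path: str | Path) -> PhysicalMap:
    contigs: list[PhysicalContig] = []
    singletons: set[str] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.rstrip()
        if not line or line.startswith("#") or line.startswith("contig_id"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 tab-separated columns")
        contig_id, cb_field, clones_field = parts
        clones = frozenset(x for x in clones_field.split(";") if x)
        if contig_id == SINGLETON:
            singletons.update(clones)
            continue
        try:
            cb_length = int(cb_field)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: cb_length {cb_field!r} not an integer") from None
        try:
            contigs.append(PhysicalContig(contig_id, cb_length, clones))
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    try:
        return PhysicalMap(contigs, frozenset(singletons))
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_physical_map(pm: PhysicalMap, path: str | Path) -> None:
    lines = ["contig_id\tcb_length\tclone_ids"]
    for c in pm.contigs:
        lines.append(f"{c.contig_id}\t{c.cb_length}\t{';'.join(sorted(c.clone_ids))}")
    if pm.singleton_clones:
        lines.append(f"{SINGLETON}\t1\t{';'.join(sorted(pm.singleton_clones))}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------


@dataclass
class AlignmentHit:
    """One row of 12-column BLAST tabular output.

    Subject coordinates are kept 1-based inclusive as printed; use
    :meth:`subject_interval` for the 0-based half-open internal convention.
    """

    query_id: str
    subject_id: str
    identity_pct: float
    align_len: int
    mismatch: int
    gapopen: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_pct <= 100.0:
            raise FormatError(f"identity {self.identity_pct} outside [0, 100]")
        if self.align_len < 1:
            raise FormatError("align_len must be >= 1")
        if self.evalue < 0:
            raise FormatError("evalue must be >= 0")

    @property
    def strand(self) -> str:
        return "-" if self.subject_start > self.subject_end else "+"

    def subject_interval(self) -> tuple[int, int]:
        """0-based half-open subject interval regardless of strand."""
        lo, hi = sorted((self.subject_start, self.subject_end))
        return lo - 1, hi


def read_blast_tab(path: str | Path) -> list[AlignmentHit]:
    hits: list[AlignmentHit] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.rstrip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 12:
            raise FormatError(f"{path}:{lineno}: expected 12 columns, got {len(parts)}")
        try:
            hits.append(
                AlignmentHit(
                    query_id=parts[0],
                    subject_id=parts[1],
                    identity_pct=float(parts[2]),
                    align_len=int(parts[3]),
                    mismatch=int(parts[4]),
                    gapopen=int(parts[5]),
                    query_start=int(parts[6]),
                    query_end=int(parts[7]),
                    subject_start=int(parts[8]),
                    subject_end=int(parts[9]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                )
            )
        except (ValueError, FormatError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    return hits


def write_blast_tab(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    lines = []
    for h in hits:
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    h.query_id,
                    h.subject_id,
                    f"{h.identity_pct:.2f}",
                    h.align_len,
                    h.mismatch,
                    h.gapopen,
                    h.query_start,
                    h.query_end,
                    h.subject_start,
                    h.subject_end,
                    f"{h.evalue:.3g}",
                    f"{h.bitscore:.1f}",
                )
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
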