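"""Core data model and on-disk formats.

Position tables hold per-site read counts for one population x gene locus,
the downstream representation of a pool-seq pileup.  All coordinates are
1-based closed intervals, matching pileup convention.  All formats are
plain TSV with ``#``-prefixed metadata lines.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO

BASES = "ACGT"
BASE_TO_INDEX = {b: i for i, b in enumerate(BASES)}
N_CODE = 4  # sequence code for an ambiguous/unknown base

__all__ = [
    "BASES",
    "BASE_TO_INDEX",
    "MaskState",
    "PositionRecord",
    "PositionTable",
    "SNP",
    "Segment",
    "GeneAnnotation",
    "seq_to_codes",
    "codes_to_seq",
    "read_position_table",
    "write_position_table",
    "read_annotation",
    "write_annotation",
    "read_fasta",
    "write_fasta",
]


class FormatError(ValueError):
    """A file violated the expected table/annotation format."""


class MaskState(enum.IntEnum):
    PASS = 0
    LOW_DEPTH = 1
    LOW_QUALITY = 2


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode an ACGTN string as uint8 codes (A=0..T=3, N=4)."""
    table = np.full(256, 255, dtype=np.uint8)
    for b, i in BASE_TO_INDEX.items():
        table[ord(b)] = i
    table[ord("N")] = N_CODE
    codes = table[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"unsupported base {bad!r}; only A/C/G/T/N accepted")
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    alphabet = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return alphabet[codes].tobytes().decode("ascii")


@dataclass
class PositionRecord:
    """One reference position of one population's pool."""

    gene_id: str
    position: int  # 1-based
    ref_base: str
    depth: int
    base_counts: tuple[int, int, int, int]  # A, C, G, T
    qual_masked: bool
    mask_state: MaskState = MaskState.PASS


class PositionTable:
    """Per-site read counts for one population x gene, stored columnar.

    Rows are accessible as :class:`PositionRecord` views; the numpy arrays
    are the working representation for the statistics modules.
    """

    def __init__(
        self,
        gene_id: str,
        population_id: str,
        positions: np.ndarray,
        ref_codes: np.ndarray,
        depth: np.ndarray,
        counts: np.ndarray,
        qual_masked: np.ndarray,
        mask_state: np.ndarray | None = None,
    ):
        self.gene_id = gene_id
        self.population_id = population_id
        self.positions = np.asarray(positions, dtype=np.int64)
        self.ref_codes = np.asarray(ref_codes, dtype=np.uint8)
        self.depth = np.asarray(depth, dtype=np.int64)
        self.counts = np.asarray(counts, dtype=np.int64)
        self.qual_masked = np.asarray(qual_masked, dtype=bool)
        if mask_state is None:
            mask_state = np.zeros(len(self.positions), dtype=np.uint8)
        self.mask_state = np.asarray(mask_state, dtype=np.uint8)
        self.validate()

    def validate(self) -> None:
        L = len(self.positions)
        for name in ("ref_codes", "depth", "qual_masked", "mask_state"):
            if len(getattr(self, name)) != L:
                raise ValueError(f"column {name} length mismatch")
        if self.counts.shape != (L, 4):
            raise ValueError("counts must be an (L, 4) array")
        if L and self.positions[0] < 1:
            raise ValueError("positions are 1-based; found position < 1")
        if L and not np.all(np.diff(self.positions) == 1):
            raise ValueError("positions must be strictly increasing and contiguous")
        if (self.depth < 0).any() or (self.counts < 0).any():
            raise ValueError("negative depth or base count")
        if (self.counts.sum(axis=1) > self.depth).any():
            i = int(np.argmax(self.counts.sum(axis=1) > self.depth))
            raise ValueError(
                f"base counts exceed depth at position {int(self.positions[i])}"
            )

    def __len__(self) -> int:
        return len(self.positions)

    def record(self, i: int) -> PositionRecord:
        return PositionRecord(
            gene_id=self.gene_id,
            position=int(self.positions[i]),
            ref_base="ACGTN"[self.ref_codes[i]],
            depth=int(self.depth[i]),
            base_counts=tuple(int(c) for c in self.counts[i]),
            qual_masked=bool(self.qual_masked[i]),
            mask_state=MaskState(int(self.mask_state[i])),
        )

    def __iter__(self):
        return (self.record(i) for i in range(len(self)))

    def copy(self) -> "PositionTable":
        return PositionTable(
            self.gene_id,
            self.population_id,
            self.positions.copy(),
            self.ref_codes.copy(),
            self.depth.copy(),
            self.counts.copy(),
            self.qual_masked.copy(),
            self.mask_state.copy(),
        )

    def index_of(self, position: int) -> int:
        """Array index of a 1-based reference position."""
        i = int(position - self.positions[0])
        if i < 0 or i >= len(self) or self.positions[i] != position:
            raise KeyError(f"position {position} not in table")
        return i

    def __eq__(self, other) -> bool:
        if not isinstance(other, PositionTable):
            return NotImplemented
        return (
            self.gene_id == other.gene_id
            and self.population_id == other.population_id
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.ref_codes, other.ref_codes)
            and np.array_equal(self.depth, other.depth)
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.qual_masked, other.qual_masked)
            and np.array_equal(self.mask_state, other.mask_state)
        )


@dataclass
class SNP:
    """A called biallelic variant (top two bases of a polymorphic site)."""

    gene_id: str
    position: int
    major_base: str
    minor_base: str
    minor_read_fraction: float
    site_class: str = "unassigned"  # synonymous|nonsynonymous|intronic|intergenic|unassigned
    fixed_vs_outgroup: bool = False
    multiallelic: bool = False

    def with_class(self, site_class: str) -> "SNP":
        return replace(self, site_class=site_class)


SEGMENT_KINDS = ("CDS", "intron", "flank")


@dataclass(frozen=True)
class Segment:
    start: int  # 1-based, closed
    end: int
    kind: str  # CDS | intron | flank
    frame: int | None = None  # codon phase of `start` within the CDS, plus-strand order

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneAnnotation:
    gene_id: str
    total_length: int
    strand: str  # '+' or '-'
    segments: tuple[Segment, ...]
    gene_class: str  # candidate | reference
    subclass: str = "none"  # sensory | regulatory | functional | none
    networks: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.segments = tuple(self.segments)
        self.networks = frozenset(self.networks)
        self.validate()

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.gene_class not in ("candidate", "reference"):
            raise ValueError(f"{self.gene_id}: unknown gene_class {self.gene_class}")
        if self.subclass not in ("sensory", "regulatory", "functional", "none"):
            raise ValueError(f"{self.gene_id}: unknown subclass {self.subclass}")
        if (self.subclass == "none") != (self.gene_class == "reference"):
            raise ValueError(
                f"{self.gene_id}: subclass must be 'none' iff gene_class is 'reference'"
            )
        if not self.networks <= {"AREB1", "JERF1"}:
            raise ValueError(f"{self.gene_id}: unknown network label")
        segs = sorted(self.segments, key=lambda s: s.start)
        pos = 1
        for s in segs:
            if s.kind not in SEGMENT_KINDS:
                raise ValueError(f"{self.gene_id}: unknown segment kind {s.kind}")
            if s.start != pos:
                raise ValueError(
                    f"{self.gene_id}: segments must tile the locus; gap/overlap at {s.start}"
                )
            if s.end < s.start:
                raise ValueError(f"{self.gene_id}: empty segment at {s.start}")
            pos = s.end + 1
        if pos != self.total_length + 1:
            raise ValueError(
                f"{self.gene_id}: segments cover {pos - 1} bp, expected {self.total_length}"
            )
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: concatenated CDS length {self.cds_length} "
                "not divisible by 3"
            )
        self.segments = tuple(segs)

    @property
    def cds_segments(self) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.kind == "CDS")

    @property
    def cds_length(self) -> int:
        return sum(s.length for s in self.cds_segments)

    def segment_at(self, position: int) -> Segment:
        for s in self.segments:
            if s.start <= position <= s.end:
                return s
        raise KeyError(f"{self.gene_id}: position {position} outside locus")

    def cds_positions(self) -> np.ndarray:
        """1-based reference positions of the CDS in plus-strand order."""
        if not self.cds_segments:
            return np.array([], dtype=np.int64)
        return np.concatenate(
            [np.arange(s.start, s.end + 1, dtype=np.int64) for s in self.cds_segments]
        )


# ---------------------------------------------------------------------------
# Position table TSV
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "position",
    "ref_base",
    "depth",
    "count_A",
    "count_C",
    "count_G",
    "count_T",
    "qual_masked",
]


def write_position_table(table: PositionTable, path) -> None:
    table.validate()
    with open(path, "w") as fh:
        fh.write(f"#gene={table.gene_id}\n")
        fh.write(f"#population={table.population_id}\n")
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        alphabet = "ACGTN"
        for i in range(len(table)):
            c = table.counts[i]
            fh.write(
                f"{table.positions[i]}\t{alphabet[table.ref_codes[i]]}\t"
                f"{table.depth[i]}\t{c[0]}\t{c[1]}\t{c[2]}\t{c[3]}\t"
                f"{int(table.qual_masked[i])}\n"
            )


def read_position_table(path) -> PositionTable:
    meta: dict[str, str] = {}
    rows: list[tuple] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    k, v = line[1:].split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            parts = line.split("\t")
            if parts[0] == "position":  # column header
                if parts != _TABLE_COLUMNS:
                    raise FormatError(f"{path}:{lineno}: unexpected column header")
                continue
            if len(parts) != len(_TABLE_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(_TABLE_COLUMNS)} columns, "
                    f"got {len(parts)}"
                )
            try:
                pos = int(parts[0])
                ref = parts[1]
                depth = int(parts[2])
                counts = tuple(int(x) for x in parts[3:7])
                qm = bool(int(parts[7]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable row ({exc})") from exc
            if ref not in "ACGTN":
                raise FormatError(f"{path}:{lineno}: bad reference base {ref!r}")
            if depth < 0 or any(c < 0 for c in counts):
                raise FormatError(f"{path}:{lineno}: negative count")
            if sum(counts) > depth:
                raise FormatError(f"{path}:{lineno}: base counts sum above depth")
            rows.append((pos, ref, depth, counts, qm, lineno))
    if "gene" not in meta or "population" not in meta:
        raise FormatError(f"{path}: missing #gene= or #population= header")
    positions = np.array([r[0] for r in rows], dtype=np.int64)
    if len(positions) > 1 and not np.all(np.diff(positions) == 1):
        i = int(np.argmax(np.diff(positions) != 1))
        raise FormatError(
            f"{path}:{rows[i + 1][5]}: positions not increasing/contiguous"
        )
    return PositionTable(
        gene_id=meta["gene"],
        population_id=meta["population"],
        positions=positions,
        ref_codes=np.array(["ACGTN".index(r[1]) for r in rows], dtype=np.uint8),
        depth=np.array([r[2] for r in rows], dtype=np.int64),
        counts=np.array([r[3] for r in rows], dtype=np.int64).reshape(-1, 4),
        qual_masked=np.array([r[4] for r in rows], dtype=bool),
    )


# ---------------------------------------------------------------------------
# Annotation TSV: one 'gene' row per gene, one 'segment' row per segment
# ---------------------------------------------------------------------------


def write_annotation(annotations: list[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#row_type\tgene_id\tcol3\tcol4\tcol5\tcol6\tcol7\n"
            "#gene rows: gene gene_id total_length strand gene_class subclass networks\n"
            "#segment rows: segment gene_id start end kind frame .\n"
        )
        for ann in annotations:
            nets = ",".join(sorted(ann.networks)) or "-"
            fh.write(
                f"gene\t{ann.gene_id}\t{ann.total_length}\t{ann.strand}\t"
                f"{ann.gene_class}\t{ann.subclass}\t{nets}\n"
            )
            for s in ann.segments:
                frame = "." if s.frame is None else str(s.frame)
                fh.write(
                    f"segment\t{ann.gene_id}\t{s.start}\t{s.end}\t{s.kind}\t{frame}\t.\n"
                )


def read_annotation(path) -> list[GeneAnnotation]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns")
            kind, gid = parts[0], parts[1]
            if kind == "gene":
                if gid in genes:
                    raise FormatError(f"{path}:{lineno}: duplicate gene id {gid!r}")
                nets = frozenset() if parts[6] == "-" else frozenset(parts[6].split(","))
                genes[gid] = dict(
                    total_length=int(parts[2]),
                    strand=parts[3],
                    gene_class=parts[4],
                    subclass=parts[5],
                    networks=nets,
                    segments=[],
                )
                order.append(gid)
            elif kind == "segment":
                if gid not in genes:
                    raise FormatError(
                        f"{path}:{lineno}: segment row before gene row for {gid!r}"
                    )
                frame = None if parts[5] == "." else int(parts[5])
                genes[gid]["segments"].append(
                    Segment(start=int(parts[2]), end=int(parts[3]), kind=parts[4], frame=frame)
                )
            else:
                raise FormatError(f"{path}:{lineno}: unknown row type {kind!r}")
    out = []
    for gid in order:
        g = genes[gid]
        try:
            out.append(GeneAnnotation(gene_id=gid, **g))
        except ValueError as exc:
            raise FormatError(f"{path}: gene {gid}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {id: uppercased sequence}; only A/C/G/T/N allowed."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains unsupported symbols {sorted(bad)}"
            )
        out[rec.id] = seq
    return out


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
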