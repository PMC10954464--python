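"""Shared coordinate types and parsers for every external format the toolkit touches.

All genomic coordinates inside the toolkit are 0-based half-open (BED-native).
GFF3 (1-based inclusive) and SAM (1-based leftmost) are converted at the I/O
boundary and nowhere else. Parsers are strict: malformed records raise
:class:`ParseError` rather than being silently repaired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger("pletools")

NUCLEOTIDES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open span [start, end) on a chromosome or contig.

    ``strand`` is '+', '-' or '.' (unstranded). This is the universal
    coordinate currency for the whole toolkit.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"strand must be one of '+', '-', '.': {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to(self, other: "GenomicInterval") -> int | None:
        """Gap in bp between the two intervals; 0 if they overlap or touch.

        ``None`` if on different chromosomes.
        """
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence for {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignmentRecord:
    """One mapped read: name, contig, 0-based position, strand and MAPQ.

    For minus-strand reads ``pos`` is the rightmost aligned base, so that
    tagmentation reads running outward from either transposon end collapse
    near the same TTAA.
    """

    query: str
    chrom: str
    pos: int
    strand: str
    mapq: int

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")
        if self.pos < 0:
            raise ValueError("pos must be >= 0")


@dataclass
class FeatureTrack:
    """A named collection of genomic intervals, e.g. genes or CpG islands."""

    name: str
    intervals: list[GenomicInterval]
    genome_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("track name must be non-empty")
        for iv in self.intervals:
            size = self.genome_sizes.get(iv.chrom)
            if size is not None and iv.end > size:
                raise ValueError(
                    f"interval {iv} exceeds declared size of {iv.chrom} ({size})"
                )

    def total_length(self) -> int:
        """Total bp covered, counting overlapping intervals once per chrom."""
        total = 0
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs = sorted(ivs, key=lambda v: v.start)
            cur_s, cur_e = ivs[0].start, ivs[0].end
            for iv in ivs[1:]:
                if iv.start <= cur_e:
                    cur_e = max(cur_e, iv.end)
                else:
                    total += cur_e - cur_s
                    cur_s, cur_e = iv.start, iv.end
            total += cur_e - cur_s
        return total


@dataclass(frozen=True)
class BlastHit:
    """One row of 12-column BLAST tabular output, subject side as interval."""

    query: str
    interval: GenomicInterval
    pident: float
    length: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass(frozen=True)
class DomainHit:
    """One per-domain row of an HMMER domtblout table."""

    protein_id: str
    domain: str
    score: float
    length: int
    envelope: GenomicInterval  # on the protein, 0-based half-open

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("domain length must be >= 1")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str = "any") -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Whitespace inside sequences is removed and letters upper-cased. With
    ``alphabet='nucleotide'`` any letter outside {A,C,G,T,N} is an error.
    Malformed input (sequence before any header, empty record) raises
    :class:`ParseError` naming the offending line.
    """
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"line {header_line}: record {header!r} has no sequence")
        if alphabet == "nucleotide":
            bad = set(seq) - NUCLEOTIDES
            if bad:
                raise ParseError(
                    f"record {header!r}: non-nucleotide characters {sorted(bad)}"
                )
        records.append(SequenceRecord(header, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise ParseError(f"line {lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError(
                        f"line {lineno}: sequence data before any '>' header"
                    )
                chunks.append("".join(line.split()).upper())
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED / GFF3
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, name: str | None = None) -> FeatureTrack:
    """Read a BED3+ file (0-based half-open, as stored) into a FeatureTrack."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"line {lineno}: BED needs >= 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ParseError(
                    f"line {lineno}: empty or inverted interval [{start}, {end})"
                )
            strand = parts[5] if len(parts) >= 6 and parts[5] in {"+", "-"} else "."
            intervals.append(GenomicInterval(chrom, start, end, strand))
    return FeatureTrack(name or Path(path).stem, intervals)


def write_bed(track: FeatureTrack, path: str | Path, scores: Iterable[int] | None = None) -> None:
    """Write BED6 (name=track name, score column optional, default 0)."""
    scores = list(scores) if scores is not None else [0] * len(track.intervals)
    with open(path, "w") as fh:
        for iv, score in zip(track.intervals, scores):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{track.name}\t{score}\t{iv.strand if iv.strand != '.' else '+'}\n"
                if iv.strand != "."
                else f"{iv.chrom}\t{iv.start}\t{iv.end}\t{track.name}\t{score}\t.\n"
            )


def read_gff3(path: str | Path, feature_types: set[str] | None = None,
              name: str | None = None) -> FeatureTrack:
    """Read GFF3 features, converting 1-based inclusive spans to 0-based half-open."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ParseError(f"line {lineno}: GFF3 needs >= 8 columns")
            if feature_types and parts[2] not in feature_types:
                continue
            try:
                start1, end1 = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinates") from exc
            if start1 < 1 or end1 < start1:
                raise ParseError(f"line {lineno}: invalid GFF3 span {start1}..{end1}")
            strand = parts[6] if parts[6] in {"+", "-"} else "."
            intervals.append(GenomicInterval(parts[0], start1 - 1, end1, strand))
    return FeatureTrack(name or Path(path).stem, intervals)


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def read_alignments(path: str | Path) -> list[AlignmentRecord]:
    """Read mapped reads from a SAM text file via pysam.

    Unmapped records are skipped. Plus-strand reads report the leftmost
    aligned base, minus-strand reads the rightmost (see module docstring for
    why). Requires @SQ header lines covering every referenced contig.
    """
    import pysam

    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as sam:
        if not sam.header.get("SQ"):
            raise ParseError("SAM header has no @SQ lines")
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            if aln.reference_name is None:
                raise ParseError(f"read {aln.query_name}: no reference name")
            if aln.is_reverse:
                pos = aln.reference_end - 1  # rightmost aligned base
                strand = "-"
            else:
                pos = aln.reference_start
                strand = "+"
            records.append(
                AlignmentRecord(aln.query_name, aln.reference_name, pos, strand,
                                aln.mapping_quality)
            )
    return records


# ---------------------------------------------------------------------------
# BLAST tabular / HMMER domtblout
# ---------------------------------------------------------------------------

def read_blast_tab(path: str | Path) -> list[BlastHit]:
    """Read 12-column BLAST tabular output (-outfmt 6).

    Subject coordinates are converted to a 0-based half-open interval; a hit
    with sstart > send is a minus-strand hit.
    """
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ParseError(f"line {lineno}: expected 12 BLAST columns")
            try:
                sstart, send = int(parts[8]), int(parts[9])
                evalue, bits = float(parts[10]), float(parts[11])
                pident, length = float(parts[2]), int(parts[3])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed numeric field") from exc
            if sstart <= send:
                iv = GenomicInterval(parts[1], sstart - 1, send, "+")
            else:
                iv = GenomicInterval(parts[1], send - 1, sstart, "-")
            hits.append(BlastHit(parts[0], iv, pident, length, evalue, bits))
    return hits


def read_domtblout(path: str | Path) -> list[DomainHit]:
    """Read an HMMER3 per-domain table (``--domtblout``) from hmmscan.

    hmmscan convention: the target is the profile (domain), the query is the
    protein. Envelope coordinates (1-based inclusive) become 0-based half-open.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            parts = raw.split()
            if len(parts) < 22:
                raise ParseError(f"line {lineno}: truncated domtblout row")
            try:
                score = float(parts[13])
                env_from, env_to = int(parts[19]), int(parts[20])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed numeric field") from exc
            if env_from < 1 or env_to < env_from:
                raise ParseError(f"line {lineno}: invalid envelope {env_from}..{env_to}")
            hits.append(
                DomainHit(
                    protein_id=parts[3],
                    domain=parts[0],
                    score=score,
                    length=env_to - env_from + 1,
                    envelope=GenomicInterval(parts[3], env_from - 1, env_to),
                )
            )
    return hits


# ---------------------------------------------------------------------------
# PDB / newick / CSV
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path):
    """Read ATOM/HETATM records (plus REMARK energy lines) into a StructureModel.

    Energy components may be stored as ``REMARK energy Evdw <x>`` lines, the
    convention also used by the synthetic ensemble writer.
    """
    from pletools.mutagenesis import Atom, StructureModel

    energies = {"Evdw": 0.0, "Elec": 0.0, "Edesol": 0.0, "Eair": 0.0}
    atoms: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("REMARK energy"):
                parts = line.split()
                if len(parts) >= 4 and parts[2] in energies:
                    energies[parts[2]] = float(parts[3])
            elif line.startswith(("ATOM  ", "HETATM")):
                try:
                    atoms.append(
                        Atom(
                            chain=line[21].strip() or "A",
                            res_index=int(line[22:26]),
                            res_name=line[17:20].strip(),
                            atom_name=line[12:16].strip(),
                            x=float(line[30:38]),
                            y=float(line[38:46]),
                            z=float(line[46:54]),
                        )
                    )
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: malformed ATOM record") from exc
    if not atoms:
        raise ParseError(f"{path}: no ATOM records")
    return StructureModel(model_id=Path(path).stem, atoms=atoms, **energies)


def write_newick(tree, path: str | Path) -> None:
    """Serialize a scikit-bio TreeNode as newick."""
    tree.write(str(path), format="newick")


def read_ct_csv(path: str | Path, require: tuple[str, ...] = ("sample", "replicate", "Ct")) -> pd.DataFrame:
    """Read a qPCR Ct table; requires at least the named columns."""
    df = pd.read_csv(path)
    missing = [c for c in require if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df["Ct"].isna().any():
        raise ParseError(f"{path}: NaN Ct values")
    return df


def read_genome_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom<TAB>length table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"line {lineno}: expected chrom<TAB>length")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer length") from exc
    if not sizes:
        raise ParseError(f"{path}: empty genome size table")
    return sizes


def load_config(path: str | Path) -> dict[str, str]:
    """Flat key=value config file mirroring CLI flags; '#' starts a comment."""
    cfg: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"line {lineno}: expected key=value")
            key, value = line.split("=", 1)
            cfg[key.strip()] = value.strip()
    return cfg
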