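"""Mining candidate piggyBac-like elements (PLEs) from homology hits.

Pipeline stage: BLAST hits against known PLE transposases are filtered to the
top nonoverlapping loci, widened with flanking sequence, scanned for open
reading frames, and qualified by a DDE_Tnp_1_7 domain hit above score and
length thresholds. A pairwise-alignment helper transfers known structural
domain boundaries from one transposase (e.g. piggyBac) onto a newly mined one.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

from pletools.io_core import (
    BlastHit,
    DomainHit,
    GenomicInterval,
    SequenceRecord,
    revcomp,
)

logger = logging.getLogger("pletools")

__all__ = [
    "BlastHit",
    "DomainHit",
    "OrfRecord",
    "TransposonCandidate",
    "filter_hits",
    "extract_flanks",
    "find_orfs",
    "filter_domains",
    "map_domain_boundaries",
]

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass(frozen=True)
class OrfRecord:
    """An ATG-initiated open reading frame with its stop codon in-span.

    ``frame`` is +1..+3 on the forward strand, -1..-3 on the reverse;
    ``interval`` is on the forward strand of the contig in either case.
    """

    interval: GenomicInterval
    frame: int
    protein: str

    def __post_init__(self) -> None:
        if len(self.protein) * 3 + 3 != self.interval.length():
            raise ValueError("ORF span must equal 3*(protein length) + stop codon")
        if "*" in self.protein:
            raise ValueError("protein contains internal stop")


@dataclass
class TransposonCandidate:
    """A filtered locus with flanks, ORFs, domain hits and TIR calls attached."""

    locus: GenomicInterval
    orfs: list[OrfRecord] = field(default_factory=list)
    domain_hits: list[DomainHit] = field(default_factory=list)
    tirs: list = field(default_factory=list)  # TirCandidate, filled by tir_finder

    def __post_init__(self) -> None:
        for orf in self.orfs:
            if not (self.locus.start <= orf.interval.start
                    and orf.interval.end <= self.locus.end):
                raise ValueError("locus must span every ORF it contains")


def filter_hits(
    hits: list[BlastHit],
    max_e: float = 1e-5,
    n_min: int = 10,
    n_max: int = 30,
) -> list[BlastHit]:
    """Select up to ``n_max`` nonoverlapping hits with E-value < ``max_e``.

    Selection is greedy by descending bitscore; a hit overlapping (>= 1 shared
    bp, same chrom, strand-blind) an already-selected hit is discarded. Fewer
    than ``n_min`` survivors is reported as a warning, not an error.
    """
    if n_min > n_max:
        raise ValueError("n_min must be <= n_max")
    passing = [h for h in hits if h.evalue < max_e]
    # stable deterministic order: bitscore desc, then coordinates
    passing.sort(key=lambda h: (-h.bitscore, h.interval.chrom, h.interval.start,
                                h.interval.end, h.query))
    selected: list[BlastHit] = []
    for hit in passing:
        if len(selected) >= n_max:
            break
        if any(hit.interval.chrom == s.interval.chrom
               and hit.interval.start < s.interval.end
               and s.interval.start < hit.interval.end
               for s in selected):
            continue
        selected.append(hit)
    if len(selected) < n_min:
        logger.warning(
            "only %d nonoverlapping hits below E=%g (wanted >= %d)",
            len(selected), max_e, n_min,
        )
    return selected


def extract_flanks(
    hit: BlastHit,
    genome: dict[str, SequenceRecord],
    flank: int = 500,
) -> TransposonCandidate:
    """Widen a hit by ``flank`` bp on each side, clipped at contig bounds."""
    chrom = hit.interval.chrom
    if chrom not in genome:
        raise KeyError(f"contig {chrom!r} absent from genome")
    contig_len = len(genome[chrom].seq)
    start = max(0, hit.interval.start - flank)
    end = min(contig_len, hit.interval.end + flank)
    return TransposonCandidate(locus=GenomicInterval(chrom, start, end, hit.interval.strand))


def find_orfs(seq: str, min_aa: int = 1, chrom: str = "seq") -> list[OrfRecord]:
    """All ATG-to-stop ORFs in all six frames with protein length >= ``min_aa``.

    ORFs require an in-frame stop within the sequence (no open-ended ORFs);
    the reported interval includes the stop codon and is always on the
    forward strand. Result sorted by protein length descending, then by
    coordinate for determinism.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = seq.upper()
    n = len(seq)
    orfs: list[OrfRecord] = []
    for strand_seq, sign in ((seq, 1), (revcomp(seq), -1)):
        for offset in range(3):
            frame = sign * (offset + 1)
            codon_starts = range(offset, n - 2, 3)
            stops = [p for p in codon_starts
                     if _CODON_TABLE.get(strand_seq[p : p + 3]) == "*"]
            for p in codon_starts:
                if strand_seq[p : p + 3] != "ATG":
                    continue
                idx = bisect.bisect_right(stops, p)
                if idx == len(stops):
                    continue  # open-ended: no in-frame stop in sequence
                stop = stops[idx]
                protein = _translate(strand_seq[p:stop])
                if protein is None or len(protein) < min_aa:
                    continue
                s, e = p, stop + 3
                if sign == 1:
                    iv = GenomicInterval(chrom, s, e, "+")
                else:
                    iv = GenomicInterval(chrom, n - e, n - s, "-")
                orfs.append(OrfRecord(iv, frame, protein))
    orfs.sort(key=lambda o: (-len(o.protein), o.interval.start, o.frame))
    return orfs


def _translate(nt: str) -> str | None:
    """Translate a stop-free coding region; None on ambiguous codons."""
    aas = []
    for i in range(0, len(nt), 3):
        aa = _CODON_TABLE.get(nt[i : i + 3])
        if aa is None:
            return None
        aas.append(aa)
    return "".join(aas)


def filter_domains(
    hits: list[DomainHit],
    name: str = "DDE_Tnp_1_7",
    min_score: float = 150.0,
    min_len: int = 275,
) -> list[DomainHit]:
    """Keep hits matching ``name`` with score > min_score and length > min_len.

    Both inequalities are strict, following the selection rule used for
    transposase candidacy (score > 150, aligned length > 275 aa).
    """
    return [
        h for h in hits
        if h.domain == name and h.score > min_score and h.length > min_len
    ]


def map_domain_boundaries(
    ref_protein: str,
    target_protein: str,
    ref_positions: list[int],
) -> list[tuple[int, bool]]:
    """Transfer 1-based residue positions from ``ref_protein`` to ``target_protein``.

    A global pairwise alignment (BLOSUM62, gap open 10 / extend 0.5, end gaps
    penalized) is computed; each reference position maps to the target residue
    aligned to it. A reference position aligned to a gap maps to the nearest
    preceding target residue and is flagged (second tuple element True).
    Returned positions are 1-based and non-decreasing for increasing inputs.
    """
    if not ref_protein or not target_protein:
        raise ValueError("both proteins must be non-empty")
    for p in ref_positions:
        if not (1 <= p <= len(ref_protein)):
            raise ValueError(f"reference position {p} out of range 1..{len(ref_protein)}")

    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(ref_protein, target_protein)[0]
    gapped_ref, gapped_tgt = str(aln[0]), str(aln[1])

    # walk alignment columns; for each ref residue record either the target
    # residue aligned to it, or (None, count of preceding target residues)
    mapping: list[tuple[int | None, int]] = []
    t_count = 0
    for cr, ct in zip(gapped_ref, gapped_tgt):
        if ct != "-":
            t_count += 1
        if cr != "-":
            mapping.append((t_count if ct != "-" else None, t_count))

    out: list[tuple[int, bool]] = []
    for p in ref_positions:
        aligned, preceding = mapping[p - 1]
        if aligned is not None:
            out.append((aligned, False))
        else:
            out.append((max(preceding, 1), True))
    return out
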