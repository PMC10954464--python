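"""Terminal-inverted-repeat (TIR) detection by k-mer matching.

A DNA transposon's 5' and 3' ends carry inverted repeats: a segment near the
5' end reappears near the 3' end as its reverse complement. Detection follows
a k-mer scheme: generate all k-mers (default k=10) from the upstream and
downstream flanks of the candidate ORF, match every upstream k-mer against the
reverse complement of every downstream k-mer allowing up to ``max_mm``
mismatches (default 2, i.e. "fewer than 3"), group matches sharing an
anti-diagonal (i + j constant for a fixed paired segment), merge overlapping
windows into longer segments, trim each merged segment to its outermost
matching base pair, and report segments of length >= 12 bp ranked by
(length desc, mismatches asc, position).

The trim step matters: a k-window overlapping a true repeat by >= k - max_mm
bases passes on the repeat bases alone, so the raw union of passing windows
systematically overhangs the repeat by a few background bases; trimming to
the outermost matching pair restores the repeat's actual extent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from pletools.io_core import GenomicInterval, SequenceRecord, revcomp
from pletools.ple_discovery import TransposonCandidate

logger = logging.getLogger("pletools")

__all__ = [
    "FlankPair",
    "KmerMatch",
    "TirCandidate",
    "match_kmers",
    "group_and_extend",
    "find_tirs",
    "check_tsd",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class FlankPair:
    """Upstream/downstream flank sequences of a candidate ORF plus origins."""

    upstream: str
    downstream: str
    up_origin: GenomicInterval | None = None
    down_origin: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if not self.upstream or not self.downstream:
            raise ValueError("both flanks must be non-empty")


@dataclass(frozen=True)
class KmerMatch:
    """Upstream k-mer at offset i pairing downstream k-mer at offset j.

    The anti-diagonal key i + j is constant along one inverted-repeat
    segment, which is what grouping exploits.
    """

    i: int
    j: int
    k: int
    mismatches: int

    @property
    def key(self) -> int:
        return self.i + self.j


@dataclass(frozen=True)
class TirCandidate:
    """A paired 5'/3' inverted-repeat segment."""

    up_interval: GenomicInterval
    down_interval: GenomicInterval
    length: int
    mismatches: int
    up_seq: str
    down_seq: str

    def __post_init__(self) -> None:
        if self.up_interval.length() != self.down_interval.length():
            raise ValueError("paired segments must have equal length")
        if self.length != self.up_interval.length():
            raise ValueError("length must equal segment span")


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_CODE.get(c, 4) for c in seq.upper()], dtype=np.int8)


def match_kmers(pair: FlankPair, k: int = 10, max_mm: int = 2) -> list[KmerMatch]:
    """All (i, j) with Hamming(upstream[i:i+k], revcomp(downstream[j:j+k])) <= max_mm.

    k-mers containing N never match. Returns an empty list when either flank
    is shorter than k.
    """
    up = _encode(pair.upstream)
    down_rc = _encode(revcomp(pair.downstream))
    m, n = len(up), len(down_rc)
    if m < k or n < k:
        return []
    n_up = m - k + 1
    n_dn = n - k + 1
    # mm[i, x]: mismatches between upstream window i and revcomp(downstream)
    # window x, where x indexes windows of the full reverse complement; the
    # original downstream offset is j = n - k - x.
    mm = np.zeros((n_up, n_dn), dtype=np.int16)
    has_n = np.zeros((n_up, n_dn), dtype=bool)
    for t in range(k):
        u = up[t : t + n_up, None]
        d = down_rc[None, t : t + n_dn]
        mm += u != d
        has_n |= (u == 4) | (d == 4)
    ii, xx = np.nonzero((mm <= max_mm) & ~has_n)
    matches = [
        KmerMatch(i=int(i), j=int(n - k - x), k=k, mismatches=int(mm[i, x]))
        for i, x in zip(ii, xx)
    ]
    matches.sort(key=lambda t_: (t_.i, t_.j))
    return matches


def group_and_extend(
    matches: list[KmerMatch],
    pair: FlankPair,
    min_len: int = 12,
    diag_tol: int = 0,
) -> list[TirCandidate]:
    """Merge k-mer matches into paired segments and filter by length.

    Matches sharing an anti-diagonal key i + j are grouped; within a group,
    overlapping or adjacent window spans are merged, the merged span is
    trimmed to its outermost matching base pair, and mismatches are recounted
    over the trimmed span. Segments of length >= ``min_len`` are returned
    ranked by (length desc, mismatches asc, upstream offset asc).

    ``diag_tol`` > 0 additionally suppresses near-duplicate candidates from
    diagonals within the tolerance (useful for indel-staggered repeats): of
    candidates on diagonals within ``diag_tol`` whose upstream spans overlap,
    only the best-ranked is kept.
    """
    if not matches:
        return []
    up = pair.upstream.upper()
    down = pair.downstream.upper()
    n = len(down)
    k = matches[0].k

    by_key: dict[int, list[KmerMatch]] = {}
    for m_ in matches:
        by_key.setdefault(m_.key, []).append(m_)

    candidates: list[tuple[TirCandidate, int]] = []
    for key, group in by_key.items():
        starts = sorted(m_.i for m_ in group)
        # merge overlapping/adjacent windows [i, i+k)
        runs: list[tuple[int, int]] = []
        run_s, run_e = starts[0], starts[0] + k
        for i in starts[1:]:
            if i <= run_e:
                run_e = max(run_e, i + k)
            else:
                runs.append((run_s, run_e))
                run_s, run_e = i, i + k
        runs.append((run_s, run_e))
        for a, e in runs:
            seg = _trim_segment(up, down, key, a, e, k)
            if seg is None:
                continue
            a2, e2, mismatches = seg
            length = e2 - a2
            if length < min_len:
                continue
            d_s, d_e = key - e2 + k, key - a2 + k
            up_seq = up[a2:e2]
            down_seq = down[d_s:d_e]
            cand = TirCandidate(
                up_interval=_project(pair.up_origin, a2, e2, "up"),
                down_interval=_project(pair.down_origin, d_s, d_e, "down"),
                length=length,
                mismatches=mismatches,
                up_seq=up_seq,
                down_seq=down_seq,
            )
            candidates.append((cand, key))

    candidates.sort(key=lambda ck: (-ck[0].length, ck[0].mismatches,
                                    ck[0].up_interval.start))
    if diag_tol > 0:
        kept: list[tuple[TirCandidate, int]] = []
        for cand, key in candidates:
            dup = any(
                abs(key - k2) <= diag_tol
                and cand.up_interval.start < c2.up_interval.end
                and c2.up_interval.start < cand.up_interval.end
                for c2, k2 in kept
            )
            if not dup:
                kept.append((cand, key))
        candidates = kept
    return [c for c, _ in candidates]


def _trim_segment(up: str, down: str, key: int, a: int, e: int, k: int):
    """Trim merged span [a, e) on the upstream to its outermost matching pair.

    Position t in the upstream pairs with downstream position key + k - 1 - t
    (complementary bases match). Returns (a', e', mismatches) or None if no
    base pair in the span matches.
    """
    def pairs(t: int) -> bool:
        d = key + k - 1 - t
        if d < 0 or d >= len(down):
            return False
        return up[t] == revcomp(down[d])

    while a < e and not pairs(a):
        a += 1
    while e > a and not pairs(e - 1):
        e -= 1
    if e <= a:
        return None
    mism = sum(0 if pairs(t) else 1 for t in range(a, e))
    return a, e, mism


def _project(origin: GenomicInterval | None, s: int, e: int, side: str) -> GenomicInterval:
    """Absolute genomic interval for flank-local span [s, e)."""
    if origin is None:
        return GenomicInterval(side, s, e)
    return GenomicInterval(origin.chrom, origin.start + s, origin.start + e)


def find_tirs(
    candidate: TransposonCandidate,
    genome: dict[str, SequenceRecord],
    flank: int = 2000,
    k: int = 10,
    max_mm: int = 2,
    min_len: int = 12,
    diag_tol: int = 0,
) -> TransposonCandidate:
    """End-to-end TIR search around a candidate's longest ORF.

    Extracts ``flank`` bp upstream of the ORF start and downstream of the ORF
    end (truncated with a warning at contig edges), runs the k-mer match and
    merge, and attaches the ranked :class:`TirCandidate` list to the candidate.
    """
    if not candidate.orfs:
        raise ValueError("candidate has no ORFs")
    orf = max(candidate.orfs, key=lambda o: len(o.protein))
    chrom = orf.interval.chrom
    if chrom not in genome:
        raise KeyError(f"contig {chrom!r} absent from genome")
    contig = genome[chrom].seq
    up_s = max(0, orf.interval.start - flank)
    up_e = orf.interval.start
    down_s = orf.interval.end
    down_e = min(len(contig), orf.interval.end + flank)
    if up_e - up_s < flank or down_e - down_s < flank:
        logger.warning("ORF within %d bp of contig edge; flanks truncated", flank)
    if up_e <= up_s or down_e <= down_s:
        candidate.tirs = []
        return candidate
    pair = FlankPair(
        upstream=contig[up_s:up_e],
        downstream=contig[down_s:down_e],
        up_origin=GenomicInterval(chrom, up_s, up_e),
        down_origin=GenomicInterval(chrom, down_s, down_e),
    )
    matches = match_kmers(pair, k=k, max_mm=max_mm)
    candidate.tirs = group_and_extend(matches, pair, min_len=min_len, diag_tol=diag_tol)
    return candidate


def check_tsd(
    locus: GenomicInterval,
    genome: dict[str, SequenceRecord],
    motif: str = "TTAA",
) -> tuple[bool | None, bool | None]:
    """Check for the target-site-duplication motif immediately outside a locus.

    Returns (left, right); each is True/False, or None when the contig ends
    within ``len(motif)`` bp of that side (undetermined).
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    contig = genome[locus.chrom].seq
    w = len(motif)
    left: bool | None
    right: bool | None
    if locus.start - w < 0:
        left = None
    else:
        left = contig[locus.start - w : locus.start].upper() == motif.upper()
    if locus.end + w > len(contig):
        right = None
    else:
        right = contig[locus.end : locus.end + w].upper() == motif.upper()
    return left, right
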