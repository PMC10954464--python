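"""Genome-wide integration-site analysis for TTAA-targeting transposons.

Covers the full downstream path from read alignments to biology: site calling
with read-support and MAPQ thresholds, target-sequence logos, a uniformly
random baseline over the genome, per-feature fold-change enrichment with
Fisher's exact test, the five-criterion genomic-safe-harbor (GSH) classifier,
and excision-footprint classification at donor sites.

Fold change follows the convention of setting the random insertion frequency
to 1: FC = (fraction of observed sites in feature) / (fraction of random
sites in feature).
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from pletools.io_core import (
    AlignmentRecord,
    FeatureTrack,
    GenomicInterval,
    SequenceRecord,
    revcomp,
)

logger = logging.getLogger("pletools")

__all__ = [
    "SiteSet",
    "FeatureTrack",
    "EnrichmentResult",
    "LogoMatrix",
    "call_sites",
    "target_logo",
    "simulate_random_sites",
    "feature_fold_change",
    "fisher_exact",
    "classify_gsh",
    "classify_footprint",
    "GSH_CRITERIA",
]


@dataclass
class SiteSet:
    """A deduplicated, sorted collection of integration sites with read support."""

    sites: list[GenomicInterval]
    support: list[int] = field(default_factory=list)
    label: str = "sites"

    def __post_init__(self) -> None:
        if not self.support:
            self.support = [1] * len(self.sites)
        if len(self.support) != len(self.sites):
            raise ValueError("support list must match sites")
        order = sorted(range(len(self.sites)),
                       key=lambda x: (self.sites[x].chrom, self.sites[x].start,
                                      self.sites[x].end))
        merged: list[GenomicInterval] = []
        counts: list[int] = []
        for idx in order:
            iv = self.sites[idx]
            if merged and merged[-1].chrom == iv.chrom and merged[-1].start == iv.start \
                    and merged[-1].end == iv.end:
                counts[-1] += self.support[idx]
            else:
                merged.append(iv)
                counts.append(self.support[idx])
        self.sites = merged
        self.support = counts

    def __len__(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 enrichment of observed vs random sites for one feature track."""

    feature: str
    n_obs_in: int
    n_obs_total: int
    n_rand_in: int
    n_rand_total: int
    fc: float
    p: float


@dataclass(frozen=True)
class LogoMatrix:
    """Per-position base frequencies and information content around sites.

    ``positions`` are offsets relative to the site start; frequencies rows
    sum to 1; information content IC = 2 + sum_b f_b log2 f_b lies in [0, 2].
    """

    positions: np.ndarray          # (w,) relative offsets
    frequencies: np.ndarray        # (w, 4) order A, C, G, T
    information: np.ndarray        # (w,) bits

    BASES = "ACGT"


def call_sites(
    alignments: list[AlignmentRecord],
    min_mapq: int = 20,
    min_reads: int = 11,
    merge_radius: int = 3,
    label: str = "sites",
) -> SiteSet:
    """Call integration sites from mapped reads.

    Alignments below ``min_mapq`` are discarded; remaining read positions are
    grouped by (chrom, pos), positions within ``merge_radius`` bp of a more
    abundant position are merged into its modal coordinate, and groups with
    at least ``min_reads`` reads (default 11, i.e. "more than 10") become
    sites. Order-invariant and idempotent in the merge.
    """
    counts: dict[tuple[str, int], int] = {}
    for aln in alignments:
        if aln.mapq < min_mapq:
            continue
        key = (aln.chrom, aln.pos)
        counts[key] = counts.get(key, 0) + 1

    # absorb positions into the modal position within +/- merge_radius,
    # processing positions by descending count (ties: leftmost first)
    merged: dict[tuple[str, int], int] = {}
    taken: set[tuple[str, int]] = set()
    for (chrom, pos), cnt in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        if (chrom, pos) in taken:
            continue
        total = cnt
        taken.add((chrom, pos))
        if merge_radius > 0:
            for delta in range(-merge_radius, merge_radius + 1):
                neighbor = (chrom, pos + delta)
                if delta != 0 and neighbor in counts and neighbor not in taken:
                    total += counts[neighbor]
                    taken.add(neighbor)
        merged[(chrom, pos)] = total

    sites = []
    support = []
    for (chrom, pos), cnt in merged.items():
        if cnt >= min_reads:
            sites.append(GenomicInterval(chrom, pos, pos + 1))
            support.append(cnt)
    return SiteSet(sites, support, label)


def target_logo(
    sites: SiteSet,
    genome: dict[str, SequenceRecord],
    halfwidth: int = 10,
) -> LogoMatrix:
    """Base-frequency/information matrix over site-centered windows.

    Windows span ``halfwidth`` bp on each side of the site interval (so a
    4 bp TTAA site yields a 4 + 2*halfwidth window). Minus-strand sites are
    reverse-complemented before counting. Sites whose window would run off
    the contig are skipped with a warning. IC uses the convention
    0*log2(0) = 0.
    """
    widths = {iv.length() for iv in sites.sites}
    if len(widths) != 1:
        raise ValueError("all sites must have equal width for a logo")
    w = widths.pop() + 2 * halfwidth
    counts = np.zeros((w, 4))
    base_idx = {b: i for i, b in enumerate(LogoMatrix.BASES)}
    used = 0
    for iv in sites.sites:
        contig = genome[iv.chrom].seq
        s, e = iv.start - halfwidth, iv.end + halfwidth
        if s < 0 or e > len(contig):
            logger.warning("site %s window exceeds contig; skipped", iv)
            continue
        window = contig[s:e].upper()
        if iv.strand == "-":
            window = revcomp(window)
        for pos, base in enumerate(window):
            if base in base_idx:
                counts[pos, base_idx[base]] += 1
        used += 1
    if used == 0:
        raise ValueError("no usable sites for logo")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    positions = np.arange(w) - halfwidth
    return LogoMatrix(positions, freqs, info)


def simulate_random_sites(
    genome_sizes: dict[str, int],
    n: int,
    seed: int = 0,
    label: str = "random",
) -> SiteSet:
    """Uniformly random 1 bp sites across the concatenated genome (seeded)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not genome_sizes:
        raise ValueError("empty genome")
    chroms = sorted(genome_sizes)
    lengths = np.array([genome_sizes[c] for c in chroms], dtype=np.int64)
    bounds = np.cumsum(lengths)
    total = int(bounds[-1])
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, total, size=n)
    sites = []
    for x in draws:
        c = int(np.searchsorted(bounds, x, side="right"))
        offset = int(x - (bounds[c - 1] if c else 0))
        sites.append(GenomicInterval(chroms[c], offset, offset + 1))
    return SiteSet(sites, [1] * n, label)


class _TrackIndex:
    """Sorted per-chrom interval arrays for fast 'within window' membership."""

    def __init__(self, track: FeatureTrack, window: int = 0):
        self.window = window
        self.by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        ivs: dict[str, list[GenomicInterval]] = {}
        for iv in track.intervals:
            ivs.setdefault(iv.chrom, []).append(iv)
        for chrom, lst in ivs.items():
            lst.sort(key=lambda v: v.start)
            starts = [v.start - window for v in lst]
            # running maximum of ends handles nested intervals
            ends = []
            running = -1
            for v in lst:
                running = max(running, v.end + window)
                ends.append(running)
            self.by_chrom[chrom] = (starts, ends)

    def hits(self, site: GenomicInterval) -> bool:
        entry = self.by_chrom.get(site.chrom)
        if entry is None:
            return False
        starts, ends = entry
        idx = bisect_right(starts, site.end - 1)  # last interval starting before site end
        if idx == 0:
            return False
        return ends[idx - 1] > site.start


def feature_fold_change(
    obs: SiteSet,
    rand: SiteSet,
    track: FeatureTrack,
    window: int = 0,
) -> EnrichmentResult:
    """Fold change of observed vs random in-feature site fractions.

    A site is "in" the feature iff its interval overlaps a track interval
    widened by ``window`` bp on each side (``window`` > 0 is meant for point
    features such as TSSs). Significance is a two-sided Fisher exact test on
    the 2x2 table (obs in/out vs rand in/out).
    """
    if len(rand) == 0:
        raise ValueError("random baseline is empty")
    index = _TrackIndex(track, window)
    n_obs_in = sum(1 for iv in obs.sites if index.hits(iv))
    n_rand_in = sum(1 for iv in rand.sites if index.hits(iv))
    if n_rand_in == 0:
        raise ValueError("baseline empty; increase n_rand")
    fc = (n_obs_in / len(obs)) / (n_rand_in / len(rand))
    p = fisher_exact([
        [n_obs_in, len(obs) - n_obs_in],
        [n_rand_in, len(rand) - n_rand_in],
    ])
    return EnrichmentResult(track.name, n_obs_in, len(obs), n_rand_in, len(rand), fc, p)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    Sums hypergeometric probabilities of tables at most as probable as the
    observed one. A zero row or column margin gives p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a nonnegative 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0
    return float(scipy.stats.fisher_exact(t, alternative="two-sided")[1])


GSH_CRITERIA = (
    "gene_5prime_50kb",
    "cancer_gene_300kb",
    "mirna_300kb",
    "inside_transcription_unit",
    "inside_ucr",
)


def classify_gsh(
    site: GenomicInterval,
    tracks: dict[str, FeatureTrack],
) -> tuple[bool, list[str]]:
    """Five-criterion genomic-safe-harbor classification of a site.

    A site is a GSH iff, measured from the site midpoint (0 if inside):
    (i) >= 50 kb from every gene's strand-aware 5' end; (ii) >= 300 kb from
    the nearest cancer-gene interval edge; (iii) >= 300 kb from the nearest
    miRNA; (iv) outside every transcription unit; (v) outside every
    ultraconserved region. Returns the verdict plus the failed criteria.
    """
    required = {"gene", "cancer_gene", "mirna", "transcription_unit", "ucr"}
    missing = required - tracks.keys()
    if missing:
        raise ValueError(f"missing GSH tracks: {sorted(missing)}")
    mid = site.midpoint
    failed: list[str] = []

    # (i) strand-aware gene 5' ends
    min_d = None
    for iv in tracks["gene"].intervals:
        if iv.chrom != site.chrom:
            continue
        tss = iv.start if iv.strand != "-" else iv.end - 1
        dist = abs(mid - tss)
        min_d = dist if min_d is None else min(min_d, dist)
    if min_d is not None and min_d < 50_000:
        failed.append("gene_5prime_50kb")

    for key, crit, radius in (
        ("cancer_gene", "cancer_gene_300kb", 300_000),
        ("mirna", "mirna_300kb", 300_000),
    ):
        min_d = None
        for iv in tracks[key].intervals:
            if iv.chrom != site.chrom:
                continue
            if iv.start <= mid < iv.end:
                dist = 0
            else:
                dist = min(abs(mid - iv.start), abs(mid - (iv.end - 1)))
            min_d = dist if min_d is None else min(min_d, dist)
        if min_d is not None and min_d < radius:
            failed.append(crit)

    for key, crit in (
        ("transcription_unit", "inside_transcription_unit"),
        ("ucr", "inside_ucr"),
    ):
        if any(iv.chrom == site.chrom and iv.start < site.end and site.start < iv.end
               for iv in tracks[key].intervals):
            failed.append(crit)

    return (not failed, failed)


def classify_footprint(
    junction_seq: str,
    left_flank: str,
    right_flank: str,
    motif: str = "TTAA",
) -> str:
    """Classify a donor-site junction after transposon excision.

    'seamless' iff the junction restores left_flank + motif + right_flank
    exactly (excision without a trace); 'insertion' if a contiguous block of
    extra bases remains between the flanks; 'deletion' if flank/motif bases
    were lost as one contiguous block; 'other' otherwise.
    """
    if not junction_seq:
        raise ValueError("empty junction sequence")
    if not motif:
        raise ValueError("motif must be non-empty")
    expected = (left_flank + motif + right_flank).upper()
    junction = junction_seq.upper()
    if junction == expected:
        return "seamless"

    shorter = min(len(junction), len(expected))
    lcp = 0
    while lcp < shorter and junction[lcp] == expected[lcp]:
        lcp += 1
    lcs = 0
    while lcs < shorter and junction[-1 - lcs] == expected[-1 - lcs]:
        lcs += 1

    if len(junction) > len(expected) and lcp + lcs >= len(expected):
        return "insertion"
    if len(junction) < len(expected) and lcp + lcs >= len(junction):
        return "deletion"
    return "other"
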