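"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure, seeded function: the same configuration gives
byte-identical output, and every generator draws from its own substream of
the master seed so adding one never perturbs another. Truth records carry
all planted coordinates and parameters, so downstream tests never need to
re-derive ground truth from the generated data.

A note on planted inverted repeats: the TTAA target-site duplication is its
own reverse complement, so the TSD copies flanking a planted element pair
with each other and extend the detectable inverted repeat by 4 bp on each
end. Truth records therefore distinguish the planted TIR proper from the
maximal detectable paired repeat (TSD-extended). Plants are made "crisp":
the base pair immediately outside the maximal repeat is forced to mismatch,
so detectors recover exactly the planted extent rather than a few lucky
background bases more.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pletools.io_core import FeatureTrack, GenomicInterval, SequenceRecord, revcomp
from pletools.integration import SiteSet
from pletools.mutagenesis import Atom, StructureModel

logger = logging.getLogger("pletools")

__all__ = [
    "SimConfig",
    "make_genome_with_element",
    "plant_inverted_repeat",
    "make_tracks",
    "simulate_sites",
    "expected_fc",
    "simulate_reads",
    "make_docking_ensemble",
    "simulate_qpcr",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# substream tags so each generator has an independent RNG stream
_STREAM = {"genome": 1, "tracks": 2, "sites": 3, "reads": 4, "ensemble": 5, "qpcr": 6}


@dataclass
class SimConfig:
    """Study conditions for all generators (defaults = the emulated study)."""

    seed: int = 0
    # genome/element
    contig_len: int = 8000
    orf_aa: int = 626            # transposase length, amino acids
    tir_len: int = 16
    tir_mismatches: int = 0
    tsd_motif: str = "TTAA"
    tir_orf_gap: int = 60        # bp between TIR and ORF on each side
    # integration sites
    n_sites: int = 2000
    theta: dict = field(default_factory=dict)   # feature name -> enrichment
    # reads
    reads_per_site: int = 15
    mapq: int = 60
    read_len: int = 50
    pos_jitter: int = 0
    # docking ensemble
    n_models: int = 12
    n_residues: int = 40
    planted_contacts: tuple = (10, 11, 12)
    contact_fraction: float = 0.8
    coord_jitter: float = 0.3    # Angstrom
    n_conformations: int = 1     # distinct docking poses (clusters)
    conformation_shift: float = 20.0  # Angstrom between pose centroids
    # qPCR
    true_copies_per_cell: float = 3.2
    sigma_ct: float = 0.1


def _rng(cfg_seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([cfg_seed, _STREAM[stream]])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


# ---------------------------------------------------------------------------
# genome with planted element
# ---------------------------------------------------------------------------

def _random_orf(rng: np.random.Generator, n_aa: int) -> str:
    """ATG + (n_aa - 1) random non-stop, non-ATG codons + TAA stop."""
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    while len(codons) < n_aa:
        c = _random_seq(rng, 3)
        if c in stops or c == "ATG":
            continue
        codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _detectable_mismatch_positions(
    length: int,
    mismatches: int,
    rng: np.random.Generator,
    k: int = 10,
    max_mm: int = 2,
    lo: int | None = None,
    hi: int | None = None,
) -> list[int]:
    """Interior mismatch positions keeping a planted repeat fully detectable.

    Positions are drawn from [1, length - 1) (segment ends always match, so
    end-trimming cannot shorten the plant). For repeats long enough to be
    reportable (length >= 12) placement is rejection-sampled until the union
    of k-windows carrying <= ``max_mm`` mismatches covers the whole segment;
    otherwise the k-mer rule itself could truncate or miss the plant.
    Shorter repeats are undetectable by design and get unconstrained interior
    positions.
    """
    if mismatches == 0:
        return []
    if length < mismatches + 2:
        raise ValueError("repeat too short for requested mismatches")
    interior = np.arange(lo if lo is not None else 1,
                         hi if hi is not None else length - 1)
    if len(interior) < mismatches:
        raise ValueError("allowed mismatch range too narrow")
    for _ in range(5000):
        cand = sorted(int(p) for p in rng.choice(interior, size=mismatches,
                                                 replace=False))
        if length < 12:
            return cand
        passing = [
            w for w in range(length - k + 1)
            if sum(1 for p in cand if w <= p < w + k) <= max_mm
        ]
        covered: set[int] = set()
        for w in passing:
            covered.update(range(w, w + k))
        if covered == set(range(length)):
            return cand
    raise RuntimeError(
        f"no detectable placement of {mismatches} mismatches in {length} bp"
    )


def plant_inverted_repeat(
    up: str,
    down: str,
    length: int,
    mismatches: int,
    rng: np.random.Generator,
    up_pos: int | None = None,
    down_pos: int | None = None,
    k: int = 10,
) -> tuple[str, str, dict]:
    """Plant an inverted repeat of ``length`` bp into a flank pair.

    The repeat segment S replaces up[up_pos:up_pos+length]; revcomp(S) with
    ``mismatches`` interior substitutions replaces down[down_pos:...].
    Mismatch positions keep the plant fully detectable under the k-mer rule
    (see :func:`_detectable_mismatch_positions`). Boundaries are crisp: the
    ``k`` base pairs beyond each end along the plant's anti-diagonal are
    forced to mismatch, so no k-window straddling the boundary can drag
    background bases into the reported segment. Returns the modified flanks
    and a truth dict with flank-local coordinates.
    """
    if length > min(len(up), len(down)) - 2:
        raise ValueError("flanks too short for plant")
    if up_pos is None:
        up_pos = int(rng.integers(1, len(up) - length))
    if down_pos is None:
        down_pos = int(rng.integers(1, len(down) - length))
    seg = _random_seq(rng, length)

    rc = list(revcomp(seg))
    mm_positions = _detectable_mismatch_positions(length, mismatches, rng, k=k)
    # position p of the paired segment corresponds to rc index length-1-p
    for p in mm_positions:
        idx = length - 1 - p
        choices = [b for b in "ACGT" if b != rc[idx]]
        rc[idx] = choices[int(rng.integers(0, 3))]
    rc_str = "".join(rc)

    up_l = list(up)
    down_l = list(down)
    up_l[up_pos : up_pos + length] = list(seg)
    down_l[down_pos : down_pos + length] = list(rc_str)

    # crisp boundaries: up[t] pairs with down[down_pos + up_pos + length-1 - t];
    # force the k pairs beyond each end to mismatch
    def force_mismatch(u_idx: int, d_idx: int) -> None:
        if 0 <= u_idx < len(up_l) and 0 <= d_idx < len(down_l):
            while up_l[u_idx] == _COMPLEMENT[down_l[d_idx]]:
                down_l[d_idx] = str(_BASES[int(rng.integers(0, 4))])

    for x in range(1, k + 1):
        force_mismatch(up_pos - x, down_pos + length - 1 + x)   # outside left end
        force_mismatch(up_pos + length - 1 + x, down_pos - x)   # outside right end

    truth = {
        "up_pos": up_pos,
        "down_pos": down_pos,
        "length": length,
        "mismatches": mismatches,
        "mismatch_positions": mm_positions,
        "up_seq": seg,
        "down_seq": rc_str,
    }
    return "".join(up_l), "".join(down_l), truth


def _paired_runs(up: str, down: str, k: int = 10, max_mm: int = 2,
                 min_len: int = 12) -> list[tuple[int, int, int]]:
    """Maximal trimmed inverted-repeat segments between two flanks.

    Generator-internal scan (independent code from the detector module) used
    to police the synthetic background: returns (up_start, up_end, key)
    per segment, where key = i + j is the anti-diagonal of the pairing.
    """
    b2i = {"A": 0, "C": 1, "G": 2, "T": 3}
    u = np.array([b2i.get(c, 4) for c in up], dtype=np.int8)
    d = np.array([b2i.get(c, 4) for c in down], dtype=np.int8)
    m, n = len(u), len(d)
    if m < k or n < k:
        return []
    # match[t, s]: up[t] pairs down[s] (complementary); N never pairs
    comp = np.array([3, 2, 1, 0, 5], dtype=np.int8)
    runs: list[tuple[int, int, int]] = []
    for key in range(0, m + n - 2 * k + 1):
        t_lo = max(0, key + k - 1 - (n - 1))
        t_hi = min(m - 1, key + k - 1)
        ts = np.arange(t_lo, t_hi + 1)
        ss = key + k - 1 - ts
        pairmatch = u[ts] == comp[d[ss]]
        L = len(ts)
        if L < k:
            continue
        win = np.convolve((~pairmatch).astype(int), np.ones(k, dtype=int), "valid")
        passing = win <= max_mm
        covered = np.zeros(L, dtype=bool)
        for w in np.nonzero(passing)[0]:
            covered[w : w + k] = True
        # maximal covered runs, trimmed to outermost matching pair
        idx = 0
        while idx < L:
            if not covered[idx]:
                idx += 1
                continue
            end = idx
            while end < L and covered[end]:
                end += 1
            a, e = idx, end
            while a < e and not pairmatch[a]:
                a += 1
            while e > a and not pairmatch[e - 1]:
                e -= 1
            if e - a >= min_len:
                runs.append((int(ts[a]), int(ts[e - 1]) + 1, key))
            idx = end
    return runs


def make_genome_with_element(cfg: SimConfig) -> tuple[SequenceRecord, dict]:
    """A random contig with one planted transposon: TSD+TIR+ORF+TIR'+TSD.

    Element layout on the forward strand:
    ``TSD  5'TIR  gap  ORF  gap  revcomp(5'TIR with mismatches)  TSD``.
    Because the TSD is self-reverse-complementary it extends the detectable
    inverted repeat; the truth record reports both the TIR proper and the
    TSD-extended maximal repeat, with crisp outer boundaries.
    """
    rng = _rng(cfg.seed, "genome")
    orf_nt = _random_orf(rng, cfg.orf_aa)
    tsd = cfg.tsd_motif.upper()
    element_len = 2 * len(tsd) + 2 * cfg.tir_len + 2 * cfg.tir_orf_gap + len(orf_nt)
    margin = 2100  # room for full 2 kb flanks around the ORF
    if cfg.contig_len < element_len + 2 * margin - 2 * 2000 + 200:
        raise ValueError("contig too short for element plus flanks")

    tir5 = _random_seq(rng, cfg.tir_len)
    tir3 = list(revcomp(tir5))
    # mismatch positions are expressed on the TSD-extended paired segment
    # (length E = |TSD| + tir_len); keep them inside the TIR, never at the
    # segment's last pairing position, and fully detectable
    ext_len = len(tsd) + cfg.tir_len
    mm_positions = _detectable_mismatch_positions(
        ext_len, cfg.tir_mismatches, rng, lo=len(tsd), hi=ext_len - 1,
    )
    for p in mm_positions:
        q = ext_len - 1 - p  # index within the downstream extended segment = TIR3
        choices = [b for b in "ACGT" if b != tir3[q]]
        tir3[q] = choices[int(rng.integers(0, 3))]
    tir3_str = "".join(tir3)

    if cfg.tir_orf_gap < 3:
        raise ValueError("tir_orf_gap must be >= 3")
    left_bg_len = max(100, (cfg.contig_len - element_len) // 2)
    # in-frame stop at the end of the 5' gap: upstream ORFs in the planted
    # frame terminate there, so the planted ORF is the longest by construction
    gap5 = _random_seq(rng, cfg.tir_orf_gap - 3) + "TAA"
    contig = list(
        _random_seq(rng, left_bg_len)
        + tsd + tir5 + gap5
        + orf_nt
        + _random_seq(rng, cfg.tir_orf_gap) + tir3_str + tsd
        + _random_seq(rng, cfg.contig_len - left_bg_len - element_len)
    )

    tsd5_s = left_bg_len
    tir5_s = tsd5_s + len(tsd)
    orf_s = tir5_s + cfg.tir_len + cfg.tir_orf_gap
    orf_e = orf_s + len(orf_nt)
    tir3_s = orf_e + cfg.tir_orf_gap
    tir3_e = tir3_s + cfg.tir_len
    tsd3_e = tir3_e + len(tsd)

    # crisp boundaries of the TSD-extended repeat to k-window depth: the 10
    # base pairs beyond each end along the plant's anti-diagonal are forced
    # to mismatch, so no straddling window extends the reported segment
    def force_mismatch(u_idx: int, d_idx: int) -> None:
        if 0 <= u_idx < len(contig) and 0 <= d_idx < len(contig):
            while contig[u_idx] == _COMPLEMENT[contig[d_idx]]:
                contig[d_idx] = str(_BASES[int(rng.integers(0, 4))])

    for x in range(1, 11):
        force_mismatch(tsd5_s - x, tsd3_e - 1 + x)                    # outer
        force_mismatch(tir5_s + cfg.tir_len - 1 + x, tir3_s - x)      # inner

    # police the background: disrupt any chance inverted repeat between the
    # ORF flanks long enough to compete with the planted one in the ranking
    ext_len = cfg.tir_len + len(tsd)
    flank = 2000
    protected = set(range(tsd5_s - 11, tir5_s + cfg.tir_len + 11)) \
        | set(range(tir3_s - 11, tsd3_e + 11)) \
        | set(range(orf_s - 3, orf_e))  # planted spans, crisp zones, ORF+stop
    for _ in range(20):
        up_s = max(0, orf_s - flank)
        down_e = min(len(contig), orf_e + flank)
        up_str = "".join(contig[up_s:orf_s])
        down_str = "".join(contig[orf_e:down_e])
        competing = [
            (a, e, key) for a, e, key in
            _paired_runs(up_str, down_str, min_len=ext_len)
            if (up_s + a, up_s + e) != (tsd5_s, tir5_s + cfg.tir_len)
        ]
        if not competing:
            break
        for a, e, key in competing:
            # break a matching base pair near the middle of the run, touching
            # whichever copy lies outside the protected spans
            mid = a + (e - a) // 2
            order = sorted(range(a, e), key=lambda t: abs(t - mid))
            for t in order:
                u_pos = up_s + t
                d_pos = orf_e + (key + 10 - 1 - t)
                if contig[u_pos] != _COMPLEMENT[contig[d_pos]]:
                    continue  # already a mismatch; breaking it gains nothing
                for pos, partner in ((u_pos, d_pos), (d_pos, u_pos)):
                    if pos not in protected:
                        choices = [b for b in "ACGT"
                                   if b != contig[pos]
                                   and b != _COMPLEMENT[contig[partner]]]
                        contig[pos] = choices[int(rng.integers(0, len(choices)))]
                        break
                else:
                    continue
                break
    else:  # pragma: no cover - disruption converges quickly in practice
        raise RuntimeError("could not clear competing inverted repeats")

    truth = {
        "chrom": "synthetic_contig",
        "tsd5": (tsd5_s, tir5_s),
        "tir5": (tir5_s, tir5_s + cfg.tir_len),
        "orf": (orf_s, orf_e),
        "orf_aa": cfg.orf_aa,
        "tir3": (tir3_s, tir3_e),
        "tsd3": (tir3_e, tsd3_e),
        "element": (tir5_s, tir3_e),
        # maximal detectable paired repeat: TSD-extended on the outer side
        "repeat_up": (tsd5_s, tir5_s + cfg.tir_len),
        "repeat_down": (tir3_s, tsd3_e),
        "repeat_len": cfg.tir_len + len(tsd),
        "tir_mismatches": cfg.tir_mismatches,
        "tir5_seq": tir5,
        "tir3_seq": tir3_str,
    }
    return SequenceRecord("synthetic_contig", "".join(contig)), truth


# ---------------------------------------------------------------------------
# annotation tracks and integration sites
# ---------------------------------------------------------------------------

def make_tracks(
    genome_sizes: dict[str, int],
    spec: dict[str, tuple[int, int]],
    seed: int = 0,
) -> dict[str, FeatureTrack]:
    """Random non-pathological toy tracks: name -> (count, interval length)."""
    rng = _rng(seed, "tracks")
    tracks: dict[str, FeatureTrack] = {}
    chroms = sorted(genome_sizes)
    for name in sorted(spec):
        count, length = spec[name]
        intervals = []
        for _ in range(count):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            size = genome_sizes[chrom]
            if size <= length + 1:
                raise ValueError(f"chrom {chrom} too short for {name} features")
            start = int(rng.integers(0, size - length))
            strand = "+" if rng.integers(0, 2) else "-"
            intervals.append(GenomicInterval(chrom, start, start + length, strand))
        tracks[name] = FeatureTrack(name, intervals, dict(genome_sizes))
    return tracks


def simulate_sites(
    tracks: dict[str, FeatureTrack],
    genome_sizes: dict[str, int],
    n: int,
    theta: dict[str, float],
    seed: int = 0,
    label: str = "sim",
) -> SiteSet:
    """Integration sites from a mixture of per-feature and uniform placement.

    Each site lands inside feature f with probability theta_f (uniform within
    f's intervals, length-weighted), otherwise uniformly on the genome. The
    expected fold change for feature f is ``expected_fc``.
    """
    total_theta = sum(theta.values())
    if total_theta > 1 + 1e-12:
        raise ValueError("sum of enrichment probabilities exceeds 1")
    for name, t in theta.items():
        if t > 0 and tracks[name].total_length() == 0:
            raise ValueError(f"feature {name} has zero length but theta > 0")

    rng = _rng(seed, "sites")
    chroms = sorted(genome_sizes)
    lengths = np.array([genome_sizes[c] for c in chroms], dtype=np.int64)
    bounds = np.cumsum(lengths)
    names = sorted(theta)
    cum = np.cumsum([theta[f] for f in names])

    sites = []
    for _ in range(n):
        u = rng.random()
        feature = None
        for f, edge in zip(names, cum):
            if u < edge:
                feature = f
                break
        if feature is None:
            x = int(rng.integers(0, int(bounds[-1])))
            c = int(np.searchsorted(bounds, x, side="right"))
            pos = x - (int(bounds[c - 1]) if c else 0)
            chrom = chroms[c]
        else:
            ivs = tracks[feature].intervals
            weights = np.array([iv.length() for iv in ivs], dtype=float)
            iv = ivs[int(rng.choice(len(ivs), p=weights / weights.sum()))]
            pos = int(rng.integers(iv.start, iv.end))
            chrom = iv.chrom
        sites.append(GenomicInterval(chrom, pos, pos + 1))
    return SiteSet(sites, [1] * n, label)


def expected_fc(theta_f: float, theta_total: float, rho_f: float) -> float:
    """Mixture-model expectation FC = (theta_f + (1 - theta_total) rho_f) / rho_f."""
    if rho_f <= 0:
        raise ValueError("feature genome fraction must be positive")
    return (theta_f + (1 - theta_total) * rho_f) / rho_f


# ---------------------------------------------------------------------------
# read alignments (SAM text)
# ---------------------------------------------------------------------------

def simulate_reads(
    sites: SiteSet,
    genome_sizes: dict[str, int],
    reads_per_site: int = 15,
    mapq: int = 60,
    read_len: int = 50,
    pos_jitter: int = 0,
    n_decoys: int = 0,
    decoy_reads: int = 3,
    seed: int = 0,
) -> str:
    """SAM text with ``reads_per_site`` reads at each site (plus decoys).

    Half the reads are minus-strand, placed so their rightmost aligned base
    sits at the site position, mirroring tagmentation libraries that read
    outward from both transposon ends. ``pos_jitter`` adds +/- jitter to the
    reported breakpoint; decoys are low-count positions that must stay below
    the calling threshold.
    """
    rng = _rng(seed, "reads")
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom in sorted(genome_sizes):
        lines.append(f"@SQ\tSN:{chrom}\tLN:{genome_sizes[chrom]}")

    def emit(chrom: str, breakpoint: int, count: int, tag: str, q: int) -> None:
        size = genome_sizes[chrom]
        for r in range(count):
            jit = int(rng.integers(-pos_jitter, pos_jitter + 1)) if pos_jitter else 0
            bp = min(max(breakpoint + jit, read_len), size - read_len - 1)
            minus = r % 2 == 1
            if minus:
                flag = 16
                pos1 = bp - read_len + 2  # rightmost base = bp (0-based)
            else:
                flag = 0
                pos1 = bp + 1
            lines.append(
                f"{tag}_{chrom}_{breakpoint}_{r}\t{flag}\t{chrom}\t{pos1}\t{q}\t"
                f"{read_len}M\t*\t0\t0\t{'A' * read_len}\t*"
            )

    for iv, _support in zip(sites.sites, sites.support):
        emit(iv.chrom, iv.start, reads_per_site, "site", mapq)

    chroms = sorted(genome_sizes)
    for d in range(n_decoys):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(read_len, genome_sizes[chrom] - read_len - 1))
        emit(chrom, pos, decoy_reads, f"decoy{d}", mapq)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# docking ensembles
# ---------------------------------------------------------------------------

def _helix_coords(n_res: int) -> np.ndarray:
    """CA trace of an idealized alpha helix along z."""
    t = np.arange(n_res) * np.deg2rad(100.0)
    return np.stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n_res)], axis=1)


def make_docking_ensemble(cfg: SimConfig) -> tuple[list[StructureModel], dict]:
    """Toy protein-DNA docking poses with planted interface residues.

    The protein is a CA-trace helix (chain A), the DNA a straight chain of
    phosphate pseudo-atoms at B-DNA rise (chain B) placed ~18 A away. In a
    ``contact_fraction`` share of models the planted residues are moved to
    within contact range (3 A) of the DNA; Gaussian jitter perturbs all
    coordinates; composite-energy components are drawn around a per-model
    mean so that contact-bearing models score best.
    """
    rng = _rng(cfg.seed, "ensemble")
    base = _helix_coords(cfg.n_residues)
    dna_z = np.arange(cfg.n_residues) * 3.4
    dna = np.stack([np.full_like(dna_z, 18.0), np.zeros_like(dna_z), dna_z], axis=1)

    n_contact_models = int(round(cfg.contact_fraction * cfg.n_models))
    models: list[StructureModel] = []
    conformations = [m % cfg.n_conformations for m in range(cfg.n_models)]
    for m in range(cfg.n_models):
        has_contacts = m < n_contact_models
        coords = base.copy()
        if has_contacts:
            for r in cfg.planted_contacts:
                z = coords[r - 1, 2]
                coords[r - 1] = [15.0, 0.0, z]  # 3 A from the DNA axis line
        # alternative poses: rigid shift of the whole protein along -x/z
        coords = coords + conformations[m] * np.array(
            [-cfg.conformation_shift, 0.0, cfg.conformation_shift])
        if cfg.coord_jitter > 0:
            coords = coords + rng.normal(0.0, cfg.coord_jitter, size=coords.shape)
        atoms = [
            Atom("A", i + 1, "ALA", "CA", *coords[i]) for i in range(cfg.n_residues)
        ] + [
            Atom("B", i + 1, "DA", "P", *dna[i]) for i in range(len(dna))
        ]
        evdw = float(rng.normal(-40.0 if has_contacts else -20.0, 2.0))
        elec = float(rng.normal(-120.0, 10.0))
        edesol = float(rng.normal(-10.0, 1.0))
        eair = float(rng.normal(40.0, 5.0))
        models.append(StructureModel(f"model_{m:03d}", atoms, evdw, elec, edesol, eair))

    truth = {
        "planted_contacts": list(cfg.planted_contacts),
        "contact_models": [f"model_{m:03d}" for m in range(n_contact_models)],
        "contact_fraction": n_contact_models / cfg.n_models,
        "conformations": {f"model_{m:03d}": conformations[m]
                          for m in range(cfg.n_models)},
    }
    return models, truth


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

QPCR_SLOPE_100PCT = -3.321928094887362  # -1/log10(2): 100% amplification efficiency


def simulate_qpcr(cfg: SimConfig, n_cells: float = 1e4,
                  replicates: int = 3) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Standards and sample Ct tables from the linear qPCR model.

    Standards: seven 10-fold dilutions (10..10^7 copies) per assay target,
    Ct = intercept + slope log10(copies) + N(0, sigma_ct). The sample carries
    ``true_copies_per_cell`` transgene copies and 2 reference (RNaseP) copies
    per cell across ``n_cells`` genomes.
    """
    rng = _rng(cfg.seed, "qpcr")
    slope, intercept = QPCR_SLOPE_100PCT, 38.0
    rows = []
    for target in ("transgene", "RNaseP"):
        for level in range(1, 8):
            copies = 10.0 ** level
            for rep in range(replicates):
                ct = intercept + slope * np.log10(copies) + rng.normal(0, cfg.sigma_ct)
                rows.append({"target": target, "copies": copies,
                             "replicate": rep + 1, "Ct": float(ct)})
    standards = pd.DataFrame(rows)

    target_copies = cfg.true_copies_per_cell * n_cells
    ref_copies = 2.0 * n_cells
    rows = []
    for target, copies in (("transgene", target_copies), ("RNaseP", ref_copies)):
        for rep in range(replicates):
            ct = intercept + slope * np.log10(copies) + rng.normal(0, cfg.sigma_ct)
            rows.append({"sample": "sample_1", "target": target,
                         "replicate": rep + 1, "Ct": float(ct)})
    samples = pd.DataFrame(rows)
    truth = {"true_copies_per_cell": cfg.true_copies_per_cell,
             "slope": slope, "intercept": intercept}
    return standards, samples, truth
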