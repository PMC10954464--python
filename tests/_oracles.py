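"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package implementations: plain
loops, direct enumeration and closed forms only.
"""

from __future__ import annotations

import math

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def brute_kmer_matches(up: str, down: str, k: int = 10, max_mm: int = 2):
    """All-pairs k-mer comparison by character loops."""
    out = []
    for i in range(len(up) - k + 1):
        u = up[i : i + k]
        if "N" in u:
            continue
        for j in range(len(down) - k + 1):
            d = revcomp(down[j : j + k])
            if "N" in d:
                continue
            mm = sum(1 for a, b in zip(u, d) if a != b)
            if mm <= max_mm:
                out.append((i, j, mm))
    return out


def brute_paired_segments(up: str, down: str, k: int = 10, max_mm: int = 2,
                          min_len: int = 12):
    """Enumerate maximal trimmed inverted-repeat segment pairs per diagonal.

    Walks every anti-diagonal (constant i + j), marks k-windows within the
    per-window mismatch budget, unions them into maximal runs, trims each run
    to its outermost matching base pair, recounts mismatches, and keeps runs
    of at least ``min_len``. Returns tuples
    (up_start, up_end, down_start, down_end, length, mismatches).
    """
    m, n = len(up), len(down)
    results = []
    for key in range(0, (m - k) + (n - k) + 1):
        # upstream positions t pair with downstream position key + k - 1 - t
        t_lo = max(0, key + k - 1 - (n - 1))
        t_hi = min(m - 1, key + k - 1)
        ts = list(range(t_lo, t_hi + 1))
        if len(ts) < k:
            continue
        match = []
        for t in ts:
            d = key + k - 1 - t
            ok = up[t] != "N" and down[d] != "N" and up[t] == COMP[down[d]]
            match.append(ok)
        L = len(ts)
        covered = [False] * L
        for w in range(L - k + 1):
            # window is valid only if every base is non-N (k-mers with N never match)
            window_ok = all(up[ts[w + x]] != "N" and
                            down[key + k - 1 - ts[w + x]] != "N"
                            for x in range(k))
            if not window_ok:
                continue
            mm = sum(1 for x in range(k) if not match[w + x])
            if mm <= max_mm:
                for x in range(k):
                    covered[w + x] = True
        idx = 0
        while idx < L:
            if not covered[idx]:
                idx += 1
                continue
            end = idx
            while end < L and covered[end]:
                end += 1
            a, e = idx, end
            while a < e and not match[a]:
                a += 1
            while e > a and not match[e - 1]:
                e -= 1
            if e - a >= min_len:
                mm = sum(1 for x in range(a, e) if not match[x])
                u_s, u_e = ts[a], ts[e - 1] + 1
                d_s, d_e = key + k - 1 - ts[e - 1], key + k - 1 - ts[a] + 1
                results.append((u_s, u_e, d_s, d_e, e - a, mm))
            idx = end
    return results


def brute_orfs(seq: str, min_aa: int = 1):
    """Six-frame ATG-to-stop scan; returns (strand, start, end, protein)."""
    from Bio.Seq import Seq

    stops = {"TAA", "TAG", "TGA"}
    out = set()
    n = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for p in range(n - 2):
            if s[p : p + 3] != "ATG":
                continue
            q = p + 3
            while q + 3 <= n and s[q : q + 3] not in stops:
                q += 3
            if q + 3 > n:
                continue
            coding = s[p:q]
            if len(coding) % 3 or "N" in coding:
                continue
            protein = str(Seq(coding).translate())
            if "*" in protein or len(protein) < min_aa:
                continue
            if strand == "+":
                out.add(("+", p, q + 3, protein))
            else:
                out.add(("-", n - (q + 3), n - p, protein))
    return out


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0

    def prob(k: int) -> float:
        return (math.comb(r1, k) * math.comb(r2, c1 - k)) / math.comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = prob(k)
        # relative slack for mathematically tied tables rounded differently
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


def gsh_brute(site_mid: int, chrom: str, tracks) -> bool:
    """Direct re-statement of the five safe-harbor criteria by full scans."""
    for iv in tracks["gene"].intervals:
        if iv.chrom != chrom:
            continue
        five = iv.start if iv.strand != "-" else iv.end - 1
        if abs(site_mid - five) < 50_000:
            return False
    for name, radius in (("cancer_gene", 300_000), ("mirna", 300_000)):
        for iv in tracks[name].intervals:
            if iv.chrom != chrom:
                continue
            if iv.start <= site_mid < iv.end:
                return False
            if min(abs(site_mid - iv.start), abs(site_mid - (iv.end - 1))) < radius:
                return False
    for name in ("transcription_unit", "ucr"):
        for iv in tracks[name].intervals:
            if iv.chrom == chrom and iv.start <= site_mid < iv.end:
                return False
    return True
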