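"""Site calling, logos, random baselines, enrichment, GSH, footprints."""

import numpy as np
import pytest

from _oracles import fisher_two_sided, gsh_brute
from pletools.io_core import (
    AlignmentRecord,
    FeatureTrack,
    GenomicInterval,
    SequenceRecord,
)
from pletools.integration import (
    SiteSet,
    call_sites,
    classify_footprint,
    classify_gsh,
    feature_fold_change,
    fisher_exact,
    simulate_random_sites,
    target_logo,
)
from pletools.synthetic_data import expected_fc, make_tracks, simulate_sites


def _reads(n, pos=500, mapq=30, chrom="chr1"):
    return [AlignmentRecord(f"r{i}", chrom, pos, "+", mapq) for i in range(n)]


class TestCallSites:
    def test_eleven_reads_at_mapq_twenty_called(self):
        assert len(call_sites(_reads(11, mapq=20))) == 1

    def test_ten_reads_not_called(self):
        assert len(call_sites(_reads(10, mapq=30))) == 0

    def test_mapq_nineteen_not_called(self):
        assert len(call_sites(_reads(11, mapq=19))) == 0

    def test_jittered_positions_merge_to_mode(self):
        reads = _reads(6, pos=100) + _reads(5, pos=102)
        ss = call_sites(reads)
        assert len(ss) == 1
        assert ss.sites[0].start == 100 and ss.support[0] == 11

    def test_merge_radius_zero_disables(self):
        reads = _reads(6, pos=100) + _reads(5, pos=102)
        assert len(call_sites(reads, merge_radius=0)) == 0

    def test_permutation_invariant(self):
        rng = np.random.default_rng(2)
        reads = _reads(12, pos=100) + _reads(15, pos=5000) + _reads(4, pos=900)
        shuffled = list(reads)
        rng.shuffle(shuffled)
        a, b = call_sites(reads), call_sites(shuffled)
        assert a.sites == b.sites and a.support == b.support


class TestTargetLogo:
    def _genome_with_ttaa(self, n_sites, rng=None):
        chunks, sites = [], []
        pos = 0
        for i in range(n_sites):
            if rng is None:
                flank_l = "ACGTACGTAC"
                flank_r = "GTACGTACGT"
            else:
                b = np.array(list("ACGT"))
                flank_l = "".join(b[rng.integers(0, 4, 10)])
                flank_r = "".join(b[rng.integers(0, 4, 10)])
            chunks.append(flank_l + "TTAA" + flank_r)
            sites.append(GenomicInterval("c", pos + 10, pos + 14))
            pos += 24
        genome = {"c": SequenceRecord("c", "".join(chunks))}
        return genome, SiteSet(sites)

    def test_perfect_conservation_at_center(self):
        genome, sites = self._genome_with_ttaa(20)
        logo = target_logo(sites, genome, halfwidth=5)
        center = slice(5, 9)
        assert np.allclose(logo.information[center], 2.0)

    def test_single_site_degenerate(self):
        genome, sites = self._genome_with_ttaa(1)
        logo = target_logo(sites, genome, halfwidth=5)
        assert np.allclose(logo.information, 2.0)

    def test_random_flanks_low_information(self):
        rng = np.random.default_rng(7)
        genome, sites = self._genome_with_ttaa(1000, rng=rng)
        logo = target_logo(sites, genome, halfwidth=8)
        flank_ic = np.concatenate([logo.information[:8], logo.information[-8:]])
        assert np.all(flank_ic < 0.1)
        assert np.allclose(logo.frequencies.sum(axis=1), 1.0)


class TestRandomSites:
    def test_reproducible_and_in_bounds(self):
        sizes = {"chr1": 1000, "chr2": 3000}
        a = simulate_random_sites(sizes, 500, seed=3)
        b = simulate_random_sites(sizes, 500, seed=3)
        assert a.sites == b.sites
        for iv in a.sites:
            assert iv.end <= sizes[iv.chrom]

    def test_chrom_proportions_follow_lengths(self):
        sizes = {"A": 100_000, "B": 300_000}
        ss = simulate_random_sites(sizes, 100_000, seed=9)
        frac_a = sum(iv.chrom == "A" for iv in ss.sites) / len(ss)
        se = np.sqrt(0.25 * 0.75 / len(ss))
        assert abs(frac_a - 0.25) < 3 * se

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            simulate_random_sites({}, 10)


class TestFisherExact:
    def test_identical_rows_give_one(self):
        assert fisher_exact([[5, 7], [5, 7]]) == pytest.approx(1.0)

    def test_zero_margin(self):
        assert fisher_exact([[0, 0], [3, 4]]) == 1.0

    def test_transpose_symmetric(self):
        assert fisher_exact([[2, 9], [5, 1]]) == pytest.approx(
            fisher_exact([[2, 5], [9, 1]]), abs=1e-12)

    def test_matches_enumeration_oracle_sample(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 9, 4))
            assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
                fisher_two_sided(a, b, c, d), abs=1e-12)


class TestFoldChange:
    def test_identity_when_obs_equals_rand(self):
        sizes = {"c": 100_000}
        ss = simulate_random_sites(sizes, 500, seed=1)
        track = FeatureTrack("f", [GenomicInterval("c", 0, 50_000)])
        res = feature_fold_change(ss, ss, track)
        assert res.fc == pytest.approx(1.0) and res.p == pytest.approx(1.0)

    def test_planted_enrichment_recovered(self):
        # feature covers half the genome; theta chosen so expected FC = 2,
        # i.e. theta + (1-theta)*0.5 = 2*0.5 -> theta = 1.0... instead use
        # rho = 0.25, theta = 1/3: FC = (1/3 + 2/3 * 1/4)/(1/4) = 2
        sizes = {"c": 1_000_000}
        track = FeatureTrack("f", [GenomicInterval("c", 0, 250_000)], dict(sizes))
        theta = 1.0 / 3.0
        obs = simulate_sites({"f": track}, sizes, 2000, {"f": theta}, seed=5)
        rand = simulate_random_sites(sizes, 20_000, seed=6)
        res = feature_fold_change(obs, rand, track)
        assert expected_fc(theta, theta, 0.25) == pytest.approx(2.0)
        assert abs(res.fc - 2.0) / 2.0 < 0.1
        assert res.p < 1e-10

    def test_empty_baseline_rejected(self):
        sizes = {"c": 1000}
        obs = SiteSet([GenomicInterval("c", 10, 11)])
        rand = SiteSet([GenomicInterval("c", 900, 901)])
        track = FeatureTrack("f", [GenomicInterval("c", 0, 100)])
        with pytest.raises(ValueError, match="baseline"):
            feature_fold_change(obs, rand, track)

    def test_window_membership(self):
        sizes = {"c": 10_000}
        track = FeatureTrack("tss", [GenomicInterval("c", 5000, 5001)])
        near = SiteSet([GenomicInterval("c", 4500, 4501)])
        rand = simulate_random_sites(sizes, 5000, seed=8)
        res = feature_fold_change(near, rand, track, window=1000)
        assert res.n_obs_in == 1
        res = feature_fold_change(near, rand, track, window=100)
        assert res.n_obs_in == 0


def _random_gsh_tracks(rng, size=4_000_000):
    sizes = {"c": size}

    def rand_track(name, n, length):
        ivs = []
        for _ in range(n):
            s = int(rng.integers(0, size - length))
            strand = "+" if rng.integers(0, 2) else "-"
            ivs.append(GenomicInterval("c", s, s + length, strand))
        return FeatureTrack(name, ivs, dict(sizes))

    return {
        "gene": rand_track("gene", 8, 20_000),
        "cancer_gene": rand_track("cancer_gene", 2, 30_000),
        "mirna": rand_track("mirna", 2, 100),
        "transcription_unit": rand_track("transcription_unit", 8, 25_000),
        "ucr": rand_track("ucr", 3, 400),
    }, sizes


class TestClassifyGsh:
    def _single_gene_tracks(self):
        sizes = {"c": 3_000_000}
        gene = FeatureTrack("gene", [GenomicInterval("c", 1_000_000, 1_100_000, "+")],
                            dict(sizes))
        empty = lambda n: FeatureTrack(n, [], dict(sizes))  # noqa: E731
        return {
            "gene": gene,
            "cancer_gene": empty("cancer_gene"),
            "mirna": empty("mirna"),
            "transcription_unit": empty("transcription_unit"),
            "ucr": empty("ucr"),
        }

    def test_hand_checked_distances(self):
        tracks = self._single_gene_tracks()
        ok, failed = classify_gsh(GenomicInterval("c", 400_000, 400_001), tracks)
        assert ok and failed == []

    def test_strict_50kb_boundary(self):
        tracks = self._single_gene_tracks()
        # gene 5' end at 1,000,000 (+ strand)
        ok, failed = classify_gsh(GenomicInterval("c", 950_001, 950_002), tracks)
        assert not ok and failed == ["gene_5prime_50kb"]  # 49,999 away
        ok, _ = classify_gsh(GenomicInterval("c", 950_000, 950_001), tracks)
        assert ok  # exactly 50,000 away passes (strict >= rule)

    def test_inside_transcription_unit_fails_only_that_criterion(self):
        tracks = self._single_gene_tracks()
        sizes = {"c": 3_000_000}
        tracks["transcription_unit"] = FeatureTrack(
            "transcription_unit", [GenomicInterval("c", 2_500_000, 2_600_000)],
            dict(sizes))
        ok, failed = classify_gsh(GenomicInterval("c", 2_550_000, 2_550_001), tracks)
        assert not ok and failed == ["inside_transcription_unit"]

    def test_missing_track_named(self):
        tracks = self._single_gene_tracks()
        del tracks["mirna"]
        with pytest.raises(ValueError, match="mirna"):
            classify_gsh(GenomicInterval("c", 0, 1), tracks)

    def test_matches_brute_force_on_random_annotations(self):
        rng = np.random.default_rng(33)
        for _ in range(20):
            tracks, sizes = _random_gsh_tracks(rng)
            for _ in range(40):
                pos = int(rng.integers(0, sizes["c"]))
                site = GenomicInterval("c", pos, pos + 1)
                ok, _ = classify_gsh(site, tracks)
                assert ok == gsh_brute(pos, "c", tracks)

    def test_random_site_gsh_rate_matches_eligible_fraction(self):
        rng = np.random.default_rng(35)
        tracks, sizes = _random_gsh_tracks(rng)
        # eligible fraction by interval arithmetic over failing regions
        bad = []
        for iv in tracks["gene"].intervals:
            five = iv.start if iv.strand != "-" else iv.end - 1
            bad.append((five - 49_999, five + 50_000))
        for name in ("cancer_gene", "mirna"):
            for iv in tracks[name].intervals:
                bad.append((iv.start - 299_999, iv.end + 299_999))
        for name in ("transcription_unit", "ucr"):
            for iv in tracks[name].intervals:
                bad.append((iv.start, iv.end))
        bad = [(max(0, s), min(sizes["c"], e)) for s, e in bad]
        bad.sort()
        covered, cur_s, cur_e = 0, *bad[0]
        for s, e in bad[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
        covered += cur_e - cur_s
        eligible = 1 - covered / sizes["c"]

        n = 20_000
        ss = simulate_random_sites(sizes, n, seed=36)
        rate = sum(classify_gsh(iv, tracks)[0] for iv in ss.sites) / n
        se = np.sqrt(max(eligible * (1 - eligible), 1e-9) / n)
        assert abs(rate - eligible) <= 2 * se + 1e-9


class TestClassifyFootprint:
    def test_seamless(self):
        assert classify_footprint("GGCTTAACCT", "GGC", "CCT") == "seamless"

    def test_insertion(self):
        assert classify_footprint("GGCTTAACTTAACCT", "GGC", "CCT") == "insertion"

    def test_deletion_of_flank_base(self):
        assert classify_footprint("GGTTAACCT", "GGC", "CCT") == "deletion"

    def test_other(self):
        assert classify_footprint("GGATTTACCT", "GGC", "CCT") == "other"

    def test_empty_junction_rejected(self):
        with pytest.raises(ValueError):
            classify_footprint("", "GGC", "CCT")
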