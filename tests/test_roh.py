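import itertools

import numpy as np
import pytest

from founderhap.intervals import GenomicInterval
from founderhap.roh import (
    delimit_roh,
    extend_roh,
    intersect_regions,
    shared_homozygote_sites,
    trim_to_shared,
)
from founderhap.variant_io import Genotype

from conftest import make_track


# --- independent oracles -----------------------------------------------------

def brute_force_outer(track, index_pos):
    """Maximal het-free marker window containing the index: split at hets."""
    runs = []
    current = []
    for pos, gt in zip(track.positions, track.genotypes):
        if gt == Genotype.HET:
            runs.append(current)
            current = []
        else:
            current.append(int(pos))
    runs.append(current)
    hets = [int(p) for p, g in zip(track.positions, track.genotypes) if g == Genotype.HET]
    for run in runs:
        if index_pos in run:
            left_het = max((h for h in hets if h < index_pos), default=None)
            right_het = min((h for h in hets if h > index_pos), default=None)
            start = left_het + 1 if left_het is not None else int(track.positions[0])
            end = right_het - 1 if right_het is not None else int(track.positions[-1])
            return start, end, left_het, right_het
    raise AssertionError("index not in any het-free run")


def brute_force_shared(tracks, interval):
    """Per-site conjunction: every track hom-alt for the identical allele."""
    maps = [
        {int(p): (int(g), a) for p, g, a in zip(t.positions, t.genotypes, t.alt_alleles)}
        for t in tracks
    ]
    out = []
    for pos in sorted(set(itertools.chain.from_iterable(maps))):
        if not (interval.start <= pos <= interval.end):
            continue
        entries = [m.get(pos) for m in maps]
        if any(e is None or e[0] != Genotype.HOM_ALT for e in entries):
            continue
        if len({e[1] for e in entries}) == 1:
            out.append(pos)
    return out


def random_track(rng, n=200, sample_id="s", chrom="chrR", het_p=0.3, index_pos=None):
    positions = np.sort(rng.choice(np.arange(1, 100_000), size=n, replace=False))
    gts = rng.choice(
        [Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT],
        size=n,
        p=[(1 - het_p) / 2, het_p, (1 - het_p) / 2],
    )
    alts = rng.choice(np.array(["C", "G"], dtype=object), size=n, p=[0.8, 0.2])
    if index_pos is not None:
        positions = np.sort(np.union1d(positions, [index_pos]))
        gts = rng.choice(
            [Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT], size=len(positions),
            p=[(1 - het_p) / 2, het_p, (1 - het_p) / 2],
        )
        alts = rng.choice(np.array(["C", "G"], dtype=object), size=len(positions), p=[0.8, 0.2])
        i = int(np.searchsorted(positions, index_pos))
        gts[i] = Genotype.HOM_ALT
        alts[i] = "C"
    return make_track(positions, gts, sample_id=sample_id, chrom=chrom, alt=alts)


# --- extend ------------------------------------------------------------------

class TestExtendRoh:
    def test_hand_traced_extension(self):
        t = make_track([100, 200, 300, 400, 500], "haaah")
        ext = extend_roh(t, 300)
        assert ext.interval == GenomicInterval("chr1", 101, 499)
        assert ext.left_het_pos == 100
        assert ext.right_het_pos == 500

    def test_no_flanking_het_clips_at_track_ends(self):
        t = make_track([10, 20, 30], "ara")
        ext = extend_roh(t, 10)
        assert ext.interval == GenomicInterval("chr1", 10, 30)
        assert ext.left_het_pos is None and ext.right_het_pos is None

    def test_hom_ref_runs_do_not_break(self):
        t = make_track([10, 20, 30, 40, 50], "hrarh")
        assert extend_roh(t, 30).interval == GenomicInterval("chr1", 11, 49)

    def test_errors(self):
        t = make_track([10, 20, 30], "aha", sample_id="sampleX")
        with pytest.raises(ValueError, match="absent"):
            extend_roh(t, 15)
        with pytest.raises(ValueError, match="sampleX"):
            extend_roh(t, 20)  # het at index
        t2 = make_track([10], "r")
        with pytest.raises(ValueError, match="not homozygous non-reference"):
            extend_roh(t2, 10)

    def test_matches_bruteforce_on_random_tracks(self, rng):
        for _ in range(300):
            t = random_track(rng, n=int(rng.integers(5, 120)), index_pos=50_000)
            ext = extend_roh(t, 50_000)
            start, end, lh, rh = brute_force_outer(t, 50_000)
            assert (ext.interval.start, ext.interval.end) == (start, end)
            assert (ext.left_het_pos, ext.right_het_pos) == (lh, rh)


# --- shared homozygotes ------------------------------------------------------

class TestSharedHomozygotes:
    def test_all_hom_alt_same_allele(self):
        tracks = [make_track([250], "a", sample_id=f"s{i}") for i in range(3)]
        got = shared_homozygote_sites(tracks, GenomicInterval("chr1", 1, 1000))
        assert list(got) == [250]

    def test_site_absent_in_one_track_excluded(self):
        t1 = make_track([100, 250], "aa")
        t2 = make_track([250], "a", sample_id="s2")
        got = shared_homozygote_sites([t1, t2], GenomicInterval("chr1", 1, 1000))
        assert list(got) == [250]

    def test_differing_alt_allele_excluded(self):
        t1 = make_track([250], "a", alt=["C"])
        t2 = make_track([250], "a", sample_id="s2", alt=["G"])
        got = shared_homozygote_sites([t1, t2], GenomicInterval("chr1", 1, 1000))
        assert list(got) == []

    def test_chromosome_mismatch_rejected(self):
        t1 = make_track([250], "a")
        t2 = make_track([250], "a", sample_id="s2", chrom="chr2")
        with pytest.raises(ValueError, match="chromosome"):
            shared_homozygote_sites([t1, t2], GenomicInterval("chr1", 1, 1000))

    def test_matches_bruteforce_on_random_tracks(self, rng):
        iv = GenomicInterval("chrR", 10_000, 90_000)
        for _ in range(100):
            tracks = [
                random_track(rng, n=60, sample_id=f"s{i}", het_p=0.2)
                for i in range(int(rng.integers(2, 5)))
            ]
            got = list(shared_homozygote_sites(tracks, iv))
            assert got == brute_force_shared(tracks, iv)


# --- trim --------------------------------------------------------------------

class TestTrimToShared:
    def test_hand_traced_trim(self):
        tracks = [
            make_track([100, 200, 300, 400, 500], "haaah", sample_id=f"s{i}")
            for i in range(3)
        ]
        outer = GenomicInterval("chr1", 101, 499)
        trimmed, lo, hi, degen = trim_to_shared(outer, tracks, 300)
        assert trimmed == GenomicInterval("chr1", 200, 400)
        assert (lo, hi) == (200, 400)
        assert not degen

    def test_only_index_shared_degenerates(self):
        t1 = make_track([100, 300, 500], ["r", "a", "r"])
        t2 = make_track([100, 300, 500], ["a", "a", "r"], sample_id="s2")
        trimmed, _, _, degen = trim_to_shared(GenomicInterval("chr1", 1, 1000), [t1, t2], 300)
        assert trimmed == GenomicInterval("chr1", 300, 300)
        assert degen

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(100):
            tracks = [
                random_track(rng, n=80, sample_id=f"s{i}", index_pos=50_000)
                for i in range(3)
            ]
            outer = extend_roh(tracks[0], 50_000).interval
            trimmed, _, _, _ = trim_to_shared(outer, tracks, 50_000)
            shared = [p for p in brute_force_shared(tracks, outer)]
            expect_lo = min(shared + [50_000])
            expect_hi = max(shared + [50_000])
            assert (trimmed.start, trimmed.end) == (expect_lo, expect_hi)


# --- intersect ---------------------------------------------------------------

def _region(sample_id, trimmed, outer=None, index_pos=None):
    from founderhap.roh import ROHRegion

    outer = outer or trimmed
    index_pos = index_pos if index_pos is not None else trimmed.start
    return ROHRegion(
        sample_id=sample_id, outer=outer, trimmed=trimmed, index_pos=index_pos,
        left_het_pos=None, right_het_pos=None,
        left_shared_hom_pos=trimmed.start, right_shared_hom_pos=trimmed.end,
    )


class TestIntersectRegions:
    def test_three_region_echo(self):
        ivs = [
            GenomicInterval("chr4", 117_649_360, 131_644_865),
            GenomicInterval("chr4", 122_400_000, 123_500_000),
            GenomicInterval("chr4", 122_000_000, 123_200_000),
        ]
        regions = [_region(f"s{i}", iv, index_pos=122_722_620) for i, iv in enumerate(ivs)]
        got = intersect_regions(regions)
        assert got.interval == GenomicInterval("chr4", 122_400_000, 123_200_000)
        assert got.sample_ids == ("s0", "s1", "s2")

    def test_identical_intervals(self):
        iv = GenomicInterval("chr1", 10, 99)
        assert intersect_regions([_region("a", iv), _region("b", iv)]).interval == iv

    def test_matches_fold_oracle(self, rng):
        for _ in range(200):
            ivs = [
                GenomicInterval(
                    "chrR", 1000 - int(rng.integers(0, 900)), 1000 + int(rng.integers(0, 900))
                )
                for _ in range(int(rng.integers(2, 6)))
            ]
            regions = [_region(f"s{i}", iv, index_pos=1000) for i, iv in enumerate(ivs)]
            folded = ivs[0]
            for iv in ivs[1:]:
                folded = folded.intersect(iv)
            assert intersect_regions(regions).interval == folded


# --- whole-stage invariants --------------------------------------------------

class TestPipelineInvariants:
    def _cohort(self, rng):
        return [random_track(rng, n=150, sample_id=f"s{i}", index_pos=50_000) for i in range(3)]

    def test_containment_chain_and_index_membership(self, rng):
        for _ in range(50):
            tracks = self._cohort(rng)
            regions = [delimit_roh(t, tracks, 50_000) for t in tracks]
            shared = intersect_regions(regions, tracks)
            for r in regions:
                assert r.outer.contains_interval(r.trimmed)
                assert r.trimmed.contains(50_000)
                assert r.trimmed.contains_interval(shared.interval)
            assert shared.interval.contains(50_000)

    def test_sample_order_permutation_invariance(self, rng):
        tracks = self._cohort(rng)
        regions = [delimit_roh(t, tracks, 50_000) for t in tracks]
        shared = intersect_regions(regions, tracks)
        perm = [tracks[2], tracks[0], tracks[1]]
        regions_p = [delimit_roh(t, perm, 50_000) for t in perm]
        shared_p = intersect_regions(regions_p, perm)
        assert shared_p.interval == shared.interval
        assert shared_p.n_shared_hom_support == shared.n_shared_hom_support
        assert {r.sample_id: r.trimmed for r in regions_p} == {
            r.sample_id: r.trimmed for r in regions
        }
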