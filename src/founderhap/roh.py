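"""ROH delimitation around an index variant and cross-carrier haplotype intersection.

The procedure mirrors classical autozygosity mapping around a known
recessive variant:

1. For each carrier, extend a run of homozygosity (ROH) outwards from the
   index position until the first high-confidence heterozygote on each side
   (``extend_roh``). Homozygous-reference calls do not break a run — a run
   of homozygosity is about zygosity, not alt-ness — and sites removed by
   the confidence filter are invisible.
2. Trim each outer region back to the outermost *shared homozygote*: a
   marker at which every carrier is homozygous for the identical
   non-reference allele (``trim_to_shared``).
3. Intersect the trimmed per-carrier regions into the shared founder
   haplotype (``intersect_regions``).

Boundary conventions: the outer boundary sits one basepair inside the
flanking heterozygote (the het itself is excluded); where no flanking het
exists the boundary clips at the first/last marker of the track (there is
no evidence beyond the markers) and the region is flagged as clipped.
Trimmed endpoints are always shared-homozygote marker positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence

import numpy as np

from .intervals import GenomicInterval
from .variant_io import Genotype, MarkerTrack

__all__ = [
    "RohExtension",
    "ROHRegion",
    "SharedHaplotype",
    "extend_roh",
    "shared_homozygote_sites",
    "trim_to_shared",
    "intersect_regions",
    "delimit_roh",
]


class RohExtension(NamedTuple):
    """Outer ROH interval plus its flanking-heterozygote evidence."""

    interval: GenomicInterval
    left_het_pos: Optional[int]  # None when the run clipped at the first marker
    right_het_pos: Optional[int]


@dataclass(frozen=True)
class ROHRegion:
    """One carrier's ROH around the index variant, before and after trimming."""

    sample_id: str
    outer: GenomicInterval
    trimmed: GenomicInterval
    index_pos: int
    left_het_pos: Optional[int]
    right_het_pos: Optional[int]
    left_shared_hom_pos: Optional[int]
    right_shared_hom_pos: Optional[int]
    degenerate: bool = False  # True when no shared hom besides the index variant

    def __post_init__(self) -> None:
        if not self.outer.contains_interval(self.trimmed):
            raise ValueError(f"trimmed region not contained in outer ({self.sample_id})")
        if not self.trimmed.contains(self.index_pos):
            raise ValueError(f"index position outside trimmed region ({self.sample_id})")
        if self.left_het_pos is not None and self.left_het_pos >= self.outer.start:
            raise ValueError("left flanking het must lie outside the outer region")
        if self.right_het_pos is not None and self.right_het_pos <= self.outer.end:
            raise ValueError("right flanking het must lie outside the outer region")


@dataclass(frozen=True)
class SharedHaplotype:
    """Intersection of all carriers' trimmed ROH regions."""

    interval: GenomicInterval
    sample_ids: tuple
    n_shared_hom_support: int

    def __post_init__(self) -> None:
        if self.n_shared_hom_support < 0:
            raise ValueError("support count must be non-negative")


def extend_roh(track: MarkerTrack, index_pos: int) -> RohExtension:
    """Extend a run of homozygosity outwards from ``index_pos``.

    The track must contain a homozygous non-reference call at the index
    position. The left boundary is one basepair right of the nearest
    heterozygote left of the index (or the track's first marker position if
    there is none); the right boundary is symmetric.
    """
    pos = track.positions
    i = int(np.searchsorted(pos, index_pos))
    if i >= len(pos) or pos[i] != index_pos:
        raise ValueError(
            f"index position {index_pos} absent from track of {track.sample_id}"
        )
    gt = Genotype(int(track.genotypes[i]))
    if gt is not Genotype.HOM_ALT:
        raise ValueError(
            f"sample {track.sample_id} is {gt.name} (not homozygous non-reference) "
            f"at index position {index_pos}"
        )
    het = track.genotypes == Genotype.HET
    left_hets = np.flatnonzero(het[:i])
    right_hets = np.flatnonzero(het[i + 1 :])
    if left_hets.size:
        left_het: Optional[int] = int(pos[left_hets[-1]])
        start = left_het + 1
    else:
        left_het = None
        start = int(pos[0])
    if right_hets.size:
        right_het: Optional[int] = int(pos[i + 1 + right_hets[0]])
        end = right_het - 1
    else:
        right_het = None
        end = int(pos[-1])
    return RohExtension(GenomicInterval(track.chrom, start, end), left_het, right_het)


def shared_homozygote_sites(
    tracks: Sequence[MarkerTrack], interval: GenomicInterval
) -> np.ndarray:
    """Positions in ``interval`` where every track is hom-alt for the same allele.

    A site absent (or filtered) in any carrier cannot be a shared
    homozygote. Returns a sorted int64 position array.
    """
    if len(tracks) < 2:
        raise ValueError("shared homozygotes require at least two tracks")
    chroms = {t.chrom for t in tracks}
    if len(chroms) > 1:
        raise ValueError(f"tracks span multiple chromosomes: {sorted(chroms)}")

    acc_pos: Optional[np.ndarray] = None
    acc_alt: Optional[np.ndarray] = None
    for t in tracks:
        sel = (
            (t.genotypes == Genotype.HOM_ALT)
            & (t.positions >= interval.start)
            & (t.positions <= interval.end)
        )
        pos_t = t.positions[sel]
        alt_t = np.asarray(t.alt_alleles, dtype=object)[sel]
        if acc_pos is None:
            acc_pos, acc_alt = pos_t, alt_t
        else:
            common, ia, ib = np.intersect1d(acc_pos, pos_t, return_indices=True)
            same = acc_alt[ia] == alt_t[ib]
            acc_pos, acc_alt = common[same], acc_alt[ia][same]
        if acc_pos.size == 0:
            break
    return np.asarray(acc_pos, dtype=np.int64)


def trim_to_shared(
    outer: GenomicInterval,
    tracks: Sequence[MarkerTrack],
    index_pos: int,
) -> tuple[GenomicInterval, Optional[int], Optional[int], bool]:
    """Trim an outer ROH back to the outermost shared homozygotes inside it.

    Returns ``(trimmed, left_anchor, right_anchor, degenerate)``. The
    trimmed start is the smallest shared-homozygote position >= outer.start
    and the end the largest <= outer.end; endpoints are marker positions.
    If no shared homozygote besides the index variant exists inside the
    outer region the result degenerates to the single-point interval at the
    index and is flagged.
    """
    if not outer.contains(index_pos):
        raise ValueError("index position must lie inside the outer region")
    shared = shared_homozygote_sites(tracks, outer)
    # Anchor at the index even if a genotyping error stripped it from the set.
    anchored = np.union1d(shared, [index_pos])
    start = int(anchored[0])
    end = int(anchored[-1])
    degenerate = bool(anchored.size <= 1)
    return GenomicInterval(outer.chrom, start, end), start, end, degenerate


def delimit_roh(
    track: MarkerTrack,
    tracks: Sequence[MarkerTrack],
    index_pos: int,
) -> ROHRegion:
    """Extend-then-trim one carrier's ROH around the index variant."""
    ext = extend_roh(track, index_pos)
    trimmed, left_anchor, right_anchor, degen = trim_to_shared(ext.interval, tracks, index_pos)
    return ROHRegion(
        sample_id=track.sample_id,
        outer=ext.interval,
        trimmed=trimmed,
        index_pos=index_pos,
        left_het_pos=ext.left_het_pos,
        right_het_pos=ext.right_het_pos,
        left_shared_hom_pos=left_anchor,
        right_shared_hom_pos=right_anchor,
        degenerate=degen,
    )


def intersect_regions(
    regions: Sequence[ROHRegion],
    tracks: Optional[Sequence[MarkerTrack]] = None,
) -> SharedHaplotype:
    """Intersect the trimmed per-carrier regions into the shared haplotype.

    The interval is [max of trimmed starts, min of trimmed ends]; since every
    trimmed region contains the index position the intersection is never
    empty. When ``tracks`` are supplied the shared-homozygote support count
    inside the result is computed; otherwise it is reported as 0.
    """
    if len(regions) < 2:
        raise ValueError("need at least two regions to intersect")
    chroms = {r.trimmed.chrom for r in regions}
    if len(chroms) > 1:
        raise ValueError(f"regions span multiple chromosomes: {sorted(chroms)}")
    index_positions = {r.index_pos for r in regions}
    if len(index_positions) > 1:
        raise ValueError("regions disagree on the index position")
    start = max(r.trimmed.start for r in regions)
    end = min(r.trimmed.end for r in regions)
    assert start <= end, "regions all contain the index position; intersection cannot be empty"
    interval = GenomicInterval(regions[0].trimmed.chrom, start, end)
    support = 0
    if tracks is not None:
        support = int(shared_homozygote_sites(tracks, interval).size)
    return SharedHaplotype(
        interval=interval,
        sample_ids=tuple(r.sample_id for r in regions),
        n_shared_hom_support=support,
    )
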