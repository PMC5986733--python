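"""VCF/BED input-output and reduction of raw calls to high-confidence marker tracks.

The analysis downstream (ROH delimitation, shared-homozygote trimming) runs
on :class:`MarkerTrack` objects: one sample, one chromosome, position-sorted
biallelic-zygosity calls that passed the high-confidence filter (non-indel
SNVs with at least ``min_depth`` reads, default 10x, and a called genotype).

Tracks are array-backed (numpy) so that simulation-scale cohorts are cheap to
scan; :attr:`MarkerTrack.calls` materialises :class:`GenotypeCall` records on
demand for inspection.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from cyvcf2 import VCF

from .intervals import GenomicInterval

__all__ = [
    "Genotype",
    "VarClass",
    "GenotypeCall",
    "MarkerTrack",
    "read_vcf",
    "load_marker_tracks",
    "high_confidence_filter",
    "write_bed",
    "read_bed",
]


class Genotype(enum.IntEnum):
    """Zygosity of a diploid genotype call."""

    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


class VarClass(str, enum.Enum):
    SNV = "snv"
    INDEL = "indel"
    OTHER = "other"


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one site, with the evidence the filter consumes."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alts: Tuple[str, ...]
    genotype: Genotype
    allele_indices: Optional[Tuple[int, int]]  # VCF allele indices; None if missing
    depth: int
    qual: Optional[float]
    var_class: VarClass
    depth_from_site: bool = False  # True when per-sample DP was absent

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.genotype is Genotype.MISSING and self.allele_indices is not None:
            raise ValueError("missing genotype must not carry allele indices")

    @property
    def alt_carried(self) -> Optional[str]:
        """The alternate allele of a homozygous-alt call, else None."""
        if self.genotype is Genotype.HOM_ALT and self.allele_indices:
            return self.alts[self.allele_indices[0] - 1]
        return None


def classify_variant(ref: str, alts: Sequence[str]) -> VarClass:
    """snv iff ref and every alt are single bases; symbolic alleles are 'other'."""
    if not alts:
        return VarClass.OTHER
    for a in alts:
        if not a or a.startswith("<") or "[" in a or "]" in a or a == "*":
            return VarClass.OTHER
    if len(ref) == 1 and all(len(a) == 1 for a in alts):
        return VarClass.SNV
    return VarClass.INDEL


def classify_genotype(a: int, b: int) -> Genotype:
    """Zygosity from two allele indices; any missing allele makes the call missing.

    Two identical non-reference alleles are homozygous-alt; two different
    alleles (including two different non-reference alleles at a
    multi-allelic site) are heterozygous.
    """
    if a < 0 or b < 0:
        return Genotype.MISSING
    if a == b:
        return Genotype.HOM_REF if a == 0 else Genotype.HOM_ALT
    return Genotype.HET


@dataclass
class MarkerTrack:
    """Position-sorted high-confidence SNV calls for one sample on one chromosome."""

    sample_id: str
    chrom: str
    positions: np.ndarray  # int64, strictly increasing
    genotypes: np.ndarray  # int8, Genotype codes (never MISSING)
    ref_alleles: np.ndarray  # object
    alt_alleles: np.ndarray  # object: the allele carried if hom_alt, else site's first alt
    depths: np.ndarray  # int32
    quals: np.ndarray  # float64 (nan when absent)
    filter_tally: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n = len(self.positions)
        if not all(
            len(a) == n
            for a in (self.genotypes, self.ref_alleles, self.alt_alleles, self.depths, self.quals)
        ):
            raise ValueError("track arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError(f"track positions must be strictly increasing ({self.sample_id})")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def het_positions(self) -> np.ndarray:
        return self.positions[self.genotypes == Genotype.HET]

    def genotype_at(self, pos: int) -> Optional[Genotype]:
        i = np.searchsorted(self.positions, pos)
        if i < len(self.positions) and self.positions[i] == pos:
            return Genotype(int(self.genotypes[i]))
        return None

    @property
    def calls(self) -> List[GenotypeCall]:
        """Materialise the track as GenotypeCall records (all high-confidence SNVs)."""
        out = []
        for i in range(len(self)):
            gt = Genotype(int(self.genotypes[i]))
            ai = {Genotype.HOM_REF: (0, 0), Genotype.HET: (0, 1), Genotype.HOM_ALT: (1, 1)}[gt]
            out.append(
                GenotypeCall(
                    sample_id=self.sample_id,
                    chrom=self.chrom,
                    pos=int(self.positions[i]),
                    ref=str(self.ref_alleles[i]),
                    alts=(str(self.alt_alleles[i]),),
                    genotype=gt,
                    allele_indices=ai,
                    depth=int(self.depths[i]),
                    qual=None if np.isnan(self.quals[i]) else float(self.quals[i]),
                    var_class=VarClass.SNV,
                )
            )
        return out


def read_vcf(
    path: str | os.PathLike,
    samples: Optional[Sequence[str]] = None,
) -> Dict[Tuple[str, str], List[GenotypeCall]]:
    """Read a VCF (plain or bgzipped) into per-sample, per-chromosome call lists.

    Returns a dict keyed by ``(sample_id, chrom)``. Every record contributes
    one :class:`GenotypeCall` per requested sample; multi-allelic records are
    preserved with their allele indices. Per-sample FORMAT/DP is used when
    present; otherwise the site-level INFO/DP is recorded for every sample
    (flagged via ``depth_from_site``), and a missing depth is stored as 0.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"VCF not found: {path}")
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad files
        raise IOError(f"could not read VCF {path}: {exc}") from exc

    available = list(vcf.samples)
    if samples is not None:
        missing = [s for s in samples if s not in available]
        if missing:
            raise ValueError(
                f"sample(s) {missing} absent from {path}; available: {available}"
            )
        vcf.set_samples(list(samples))
    sample_ids = list(vcf.samples)

    out: Dict[Tuple[str, str], List[GenotypeCall]] = {}
    for var in vcf:
        alts = tuple(var.ALT)
        vclass = classify_variant(var.REF, alts)
        gts = var.genotypes  # [[a, b, phased], ...]
        fmt_dp = None
        try:
            fmt_dp = var.format("DP")
        except KeyError:
            fmt_dp = None
        site_dp = var.INFO.get("DP")
        for si, sid in enumerate(sample_ids):
            a, b = int(gts[si][0]), int(gts[si][1])
            gt = classify_genotype(a, b)
            if fmt_dp is not None and int(fmt_dp[si][0]) >= 0:
                depth, from_site = int(fmt_dp[si][0]), False
            elif site_dp is not None:
                depth, from_site = int(site_dp), True
            else:
                depth, from_site = 0, False
            call = GenotypeCall(
                sample_id=sid,
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alts=alts,
                genotype=gt,
                allele_indices=None if gt is Genotype.MISSING else (a, b),
                depth=depth,
                qual=var.QUAL,
                var_class=vclass,
                depth_from_site=from_site,
            )
            out.setdefault((sid, var.CHROM), []).append(call)
    return out


def high_confidence_filter(
    calls: Iterable[GenotypeCall], min_depth: int = 10
) -> MarkerTrack:
    """Reduce one sample's calls on one chromosome to a high-confidence track.

    Retains exactly the calls that are non-indel SNVs with depth >= min_depth
    and a non-missing genotype; order (after position sort) is preserved. The
    removal tally is attached to the returned track. Filtering an already
    filtered track again is a no-op.
    """
    calls = sorted(calls, key=lambda c: c.pos)
    if not calls:
        raise ValueError("cannot build a marker track from zero calls")
    sample_ids = {c.sample_id for c in calls}
    chroms = {c.chrom for c in calls}
    if len(sample_ids) > 1:
        raise ValueError(f"calls mix samples: {sorted(sample_ids)}")
    if len(chroms) > 1:
        raise ValueError(f"calls mix chromosomes: {sorted(chroms)}")

    tally = {
        "input": len(calls),
        "kept": 0,
        "removed_not_snv": 0,
        "removed_low_depth": 0,
        "removed_missing_gt": 0,
        "removed_duplicate_pos": 0,
    }
    pos, gt, ref, alt, dp, qual = [], [], [], [], [], []
    last_pos = -1
    for c in calls:
        if c.var_class is not VarClass.SNV:
            tally["removed_not_snv"] += 1
            continue
        if c.genotype is Genotype.MISSING:
            tally["removed_missing_gt"] += 1
            continue
        if c.depth < min_depth:
            tally["removed_low_depth"] += 1
            continue
        if c.pos == last_pos:  # split multi-allelic duplicates: first record wins
            tally["removed_duplicate_pos"] += 1
            continue
        last_pos = c.pos
        tally["kept"] += 1
        pos.append(c.pos)
        gt.append(int(c.genotype))
        ref.append(c.ref)
        carried = c.alt_carried
        alt.append(carried if carried is not None else c.alts[0])
        dp.append(c.depth)
        qual.append(np.nan if c.qual is None else c.qual)
    return MarkerTrack(
        sample_id=calls[0].sample_id,
        chrom=calls[0].chrom,
        positions=np.array(pos, dtype=np.int64),
        genotypes=np.array(gt, dtype=np.int8),
        ref_alleles=np.array(ref, dtype=object),
        alt_alleles=np.array(alt, dtype=object),
        depths=np.array(dp, dtype=np.int32),
        quals=np.array(qual, dtype=np.float64),
        filter_tally=tally,
    )


def load_marker_tracks(
    path: str | os.PathLike,
    samples: Sequence[str],
    chrom: str,
    min_depth: int = 10,
) -> List[MarkerTrack]:
    """Read a VCF and return one high-confidence track per sample for ``chrom``."""
    calls = read_vcf(path, samples=samples)
    tracks = []
    for sid in samples:
        key = (sid, chrom)
        if key not in calls:
            raise ValueError(f"sample {sid} has no calls on {chrom} in {path}")
        tracks.append(high_confidence_filter(calls[key], min_depth=min_depth))
    return tracks


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | os.PathLike,
    names: Optional[Sequence[str]] = None,
) -> None:
    """Write intervals as BED (0-based half-open), one line each.

    The 1-based inclusive interval [start, end] becomes the BED triple
    (chrom, start-1, end); reading the file back reproduces coordinates
    exactly.
    """
    if names is not None and len(names) != len(intervals):
        raise ValueError("names must match intervals in length")
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start - 1), str(iv.end)]
            if names is not None:
                cols.append(names[i])
            fh.write("\t".join(cols) + "\n")


def read_bed(path: str | os.PathLike) -> List[Tuple[GenomicInterval, Optional[str]]]:
    """Read a BED file back into 1-based inclusive intervals (+ optional name)."""
    out: List[Tuple[GenomicInterval, Optional[str]]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line in {path}: {line!r}")
            chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else None
            out.append((GenomicInterval(chrom, start0 + 1, end), name))
    return out
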