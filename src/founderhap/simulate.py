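"""Founder-descent cohort simulator with a full truth channel.

The generator emulates the data structure of a multi-sample exome VCF in
which k unrelated carriers are homozygous for the same founder allele and
share an eroded ancestral haplotype around the index variant:

* Each carrier's two chromosomes descend from the founder through
  independent lineages of ``g`` meioses. Under the Haldane (no-interference)
  crossover model the ancestral segment retained around the focal locus
  extends on each side by an Exponential(rate g per Morgan) length,
  independently per side and per lineage.
* Markers are placed by a Poisson process at an exome-like density, with a
  guaranteed marker at the index position. Inside a carrier's ancestral
  segment the carrier is homozygous for the founder allele at every marker;
  outside, genotypes are Hardy-Weinberg draws at the marker's background
  alternate-allele frequency (Beta-distributed, truncated away from 0 and
  0.5 so heterozygotes are common enough to delimit ROH sharply).
* Genotyping error flips a call to each of the other two genotypes with
  equal probability; per-sample read depth is Poisson and independent of
  genotype (a depth of zero is emitted as a missing call).

Everything is reproducible from ``(config, seed)``; the truth record stores
the per-lineage segment extents, per-carrier true ROH, and the true shared
interval (intersection of all 2k segments).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .intervals import GenomicInterval, intersect_all
from .genmap import GeneticMap
from .recessive import AnnotatedVariant
from .variant_io import Genotype, MarkerTrack

__all__ = [
    "FounderSimConfig",
    "CarrierTruth",
    "FounderSimTruth",
    "SimulatedCohort",
    "sample_segment_extents",
    "sample_shared_length_morgans",
    "simulate_cohort",
    "simulate_trio_table",
    "write_worked_example_vcf",
    "WORKED_EXAMPLE_SAMPLES",
    "WORKED_EXAMPLE_INDEX",
]

_BASES = np.array(["A", "C", "G", "T"], dtype=object)
_GT_STR = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


@dataclass
class FounderSimConfig:
    """Study conditions for the founder-descent simulator.

    Defaults mirror the analysed cohort: three homozygous carriers of a
    founder allele at chr4:122,722,620 whose most recent common ancestor
    lived ~125 generations ago, genotyped at exome-like marker density
    (~12 informative SNVs per Mb) with high mean coverage and a small
    genotyping error rate.
    """

    g: float = 125.0  # generations from founder to each carrier (per lineage)
    k: int = 3  # number of homozygous carriers
    chrom: str = "chr4"
    chrom_length_bp: int = 190_000_000
    index_pos: int = 122_722_620
    marker_density_per_mb: float = 12.0
    freq_beta_a: float = 2.0  # background alt-frequency ~ Beta(a, b)
    freq_beta_b: float = 5.0
    freq_min: float = 0.05  # truncation keeps hets informative
    freq_max: float = 0.5
    genotype_error_rate: float = 0.002
    mean_depth: float = 40.0
    n_noncarriers: int = 0
    gmap: Optional[GeneticMap] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise ValueError("g must be positive")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (1 <= self.index_pos <= self.chrom_length_bp):
            raise ValueError("index position must lie on the chromosome")
        if self.marker_density_per_mb <= 0:
            raise ValueError("marker density must be positive")
        if not (0 <= self.genotype_error_rate < 1):
            raise ValueError("genotype error rate must be in [0, 1)")

    @property
    def genetic_map(self) -> GeneticMap:
        return self.gmap if self.gmap is not None else GeneticMap(chrom=self.chrom)


@dataclass(frozen=True)
class CarrierTruth:
    sample_id: str
    segments: Tuple[GenomicInterval, GenomicInterval]  # one per lineage
    segment_extents_morgans: Tuple[Tuple[float, float], Tuple[float, float]]
    roh: GenomicInterval  # intersection of the two segments
    truncated: bool  # any segment clipped at a chromosome end


@dataclass(frozen=True)
class FounderSimTruth:
    g: float
    k: int
    seed: int
    carriers: Tuple[CarrierTruth, ...]
    shared: GenomicInterval  # intersection of all 2k segments

    def to_dict(self) -> Dict:
        return {
            "g": self.g,
            "k": self.k,
            "seed": self.seed,
            "shared": {"chrom": self.shared.chrom, "start": self.shared.start, "end": self.shared.end},
            "carriers": [
                {
                    "sample_id": c.sample_id,
                    "roh": {"start": c.roh.start, "end": c.roh.end},
                    "segments": [{"start": s.start, "end": s.end} for s in c.segments],
                    "segment_extents_morgans": [list(e) for e in c.segment_extents_morgans],
                    "truncated": c.truncated,
                }
                for c in self.carriers
            ],
        }


@dataclass
class SimulatedCohort:
    """In-memory simulated cohort; serialises to VCF text on demand."""

    config: FounderSimConfig
    truth: FounderSimTruth
    sample_ids: List[str]
    positions: np.ndarray  # int64, strictly increasing
    ref_alleles: np.ndarray  # object
    alt_alleles: np.ndarray  # object
    genotypes: np.ndarray  # (n_samples, n_markers) int8, -1/0/1/2
    depths: np.ndarray  # (n_samples, n_markers) int32

    @property
    def n_markers(self) -> int:
        return len(self.positions)

    def write_vcf(self, path: str | os.PathLike) -> None:
        """Write the cohort as uncompressed VCF 4.2 (byte-deterministic)."""
        cfg = self.config
        lines = [
            "##fileformat=VCFv4.2",
            "##source=founderhap-simulate",
            f"##contig=<ID={cfg.chrom},length={cfg.chrom_length_bp}>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(self.sample_ids),
        ]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
            for j in range(self.n_markers):
                fields = [
                    cfg.chrom,
                    str(int(self.positions[j])),
                    ".",
                    str(self.ref_alleles[j]),
                    str(self.alt_alleles[j]),
                    ".",
                    ".",
                    ".",
                    "GT:DP",
                ]
                for i in range(len(self.sample_ids)):
                    fields.append(f"{_GT_STR[int(self.genotypes[i, j])]}:{int(self.depths[i, j])}")
                fh.write("\t".join(fields) + "\n")

    def write_truth_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def tracks(self, min_depth: int = 10, samples: Optional[Sequence[str]] = None) -> List[MarkerTrack]:
        """High-confidence marker tracks (all sites are SNVs by construction)."""
        out = []
        want = list(samples) if samples is not None else self.sample_ids
        for sid in want:
            i = self.sample_ids.index(sid)
            keep = (self.genotypes[i] != Genotype.MISSING) & (self.depths[i] >= min_depth)
            out.append(
                MarkerTrack(
                    sample_id=sid,
                    chrom=self.config.chrom,
                    positions=self.positions[keep],
                    genotypes=self.genotypes[i, keep],
                    ref_alleles=self.ref_alleles[keep],
                    alt_alleles=self.alt_alleles[keep],
                    depths=self.depths[i, keep],
                    quals=np.full(int(keep.sum()), np.nan),
                    filter_tally={
                        "input": self.n_markers,
                        "kept": int(keep.sum()),
                        "removed_low_depth": int((self.depths[i] < min_depth).sum()),
                        "removed_missing_gt": int(
                            ((self.genotypes[i] == Genotype.MISSING) & (self.depths[i] >= min_depth)).sum()
                        ),
                    },
                )
            )
        return out


def sample_segment_extents(g: float, rng: np.random.Generator) -> Tuple[float, float]:
    """Left/right ancestral-segment extents (Morgans) after g meioses.

    Under Haldane's no-interference model the distance to the nearest
    crossover accumulated over g meioses is Exponential with rate g per
    Morgan, independently on each side.
    """
    if g <= 0:
        raise ValueError("g must be positive")
    left, right = rng.exponential(scale=1.0 / g, size=2)
    return float(left), float(right)


def sample_shared_length_morgans(
    g: float, k: int, rng: np.random.Generator, size: Optional[int] = None
) -> np.ndarray | float:
    """Total shared-haplotype length (Morgans) among k homozygous carriers.

    The shared interval is the intersection of 2k independently eroded
    segments: each side's extent is the minimum of 2k Exp(g) draws, i.e.
    Exp(2kg), so the total is Gamma(shape 2, rate 2kg) with mean 1/(kg).
    """
    if g <= 0 or k < 1:
        raise ValueError("need g > 0 and k >= 1")
    n = 1 if size is None else size
    total = rng.exponential(scale=1.0 / (2 * k * g), size=n) + rng.exponential(
        scale=1.0 / (2 * k * g), size=n
    )
    return float(total[0]) if size is None else total


def _truncated_beta(
    rng: np.random.Generator, a: float, b: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Rejection-sample Beta(a, b) truncated to [lo, hi]."""
    out = rng.beta(a, b, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.beta(a, b, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _segment_bp(cfg: FounderSimConfig, left_m: float, right_m: float) -> Tuple[GenomicInterval, bool]:
    """Convert per-side Morgan extents around the index into a bp interval."""
    gmap = cfg.genetic_map
    truncated = False
    if gmap.has_knots:
        cm0 = gmap.cm_at(cfg.index_pos)
        lcm, rcm = cm0 - 100.0 * left_m, cm0 + 100.0 * right_m
        if lcm < gmap.cumulative_cm[0]:
            lcm, truncated = float(gmap.cumulative_cm[0]), True
        if rcm > gmap.cumulative_cm[-1]:
            rcm, truncated = float(gmap.cumulative_cm[-1]), True
        start, end = gmap.bp_at_cm(lcm), gmap.bp_at_cm(rcm)
    else:
        per_m_bp = 100.0 / gmap.rate_cm_per_mb * 1e6  # bp per Morgan
        start = cfg.index_pos - left_m * per_m_bp
        end = cfg.index_pos + right_m * per_m_bp
    start_i, end_i = int(round(start)), int(round(end))
    if start_i < 1:
        start_i, truncated = 1, True
    if end_i > cfg.chrom_length_bp:
        end_i, truncated = cfg.chrom_length_bp, True
    return GenomicInterval(cfg.chrom, max(1, start_i), min(cfg.chrom_length_bp, max(end_i, start_i))), truncated


def simulate_cohort(config: FounderSimConfig) -> SimulatedCohort:
    """Simulate a carrier cohort (plus optional non-carriers) with truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # Marker positions: Poisson process plus a guaranteed marker at the index.
    n_expected = cfg.marker_density_per_mb * cfg.chrom_length_bp / 1e6
    n = int(rng.poisson(n_expected))
    positions = np.unique(rng.integers(1, cfg.chrom_length_bp + 1, size=n))
    positions = np.union1d(positions, [cfg.index_pos]).astype(np.int64)
    m = len(positions)
    idx = int(np.searchsorted(positions, cfg.index_pos))

    freqs = _truncated_beta(rng, cfg.freq_beta_a, cfg.freq_beta_b, cfg.freq_min, cfg.freq_max, m)
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    ref_alleles = _BASES[ref_idx]
    alt_alleles = _BASES[alt_idx]

    founder_is_alt = rng.random(m) < freqs
    founder_is_alt[idx] = True  # the index variant rides the founder haplotype

    sample_ids = [f"carrier{i + 1}" for i in range(cfg.k)] + [
        f"control{i + 1}" for i in range(cfg.n_noncarriers)
    ]
    n_samples = len(sample_ids)
    genotypes = np.empty((n_samples, m), dtype=np.int8)

    carriers: List[CarrierTruth] = []
    all_segments: List[GenomicInterval] = []
    for i in range(cfg.k):
        segs, exts = [], []
        truncated = False
        n_founder = np.zeros(m, dtype=np.int8)
        for _ in range(2):  # two lineages back to the founder
            left_m, right_m = sample_segment_extents(cfg.g, rng)
            seg, trunc = _segment_bp(cfg, left_m, right_m)
            truncated = truncated or trunc
            segs.append(seg)
            exts.append((left_m, right_m))
            covered = (positions >= seg.start) & (positions <= seg.end)
            background = rng.random(m) < freqs
            n_founder += np.where(covered, founder_is_alt, background).astype(np.int8)
        genotypes[i] = n_founder  # alt-allele count maps onto the Genotype codes
        roh = segs[0].intersect(segs[1])
        assert roh is not None  # both segments contain the index position
        carriers.append(
            CarrierTruth(
                sample_id=sample_ids[i],
                segments=(segs[0], segs[1]),
                segment_extents_morgans=(exts[0], exts[1]),
                roh=roh,
                truncated=truncated,
            )
        )
        all_segments.extend(segs)

    for i in range(cfg.k, n_samples):  # non-carriers: pure HWE background
        a1 = rng.random(m) < freqs
        a2 = rng.random(m) < freqs
        genotypes[i] = a1.astype(np.int8) + a2.astype(np.int8)

    if cfg.genotype_error_rate > 0:
        err = rng.random(genotypes.shape) < cfg.genotype_error_rate
        shift = rng.integers(1, 3, size=genotypes.shape, dtype=np.int8)
        genotypes = np.where(err, (genotypes + shift) % 3, genotypes).astype(np.int8)

    depths = rng.poisson(cfg.mean_depth, size=genotypes.shape).astype(np.int32)
    genotypes[depths == 0] = Genotype.MISSING

    truth = FounderSimTruth(
        g=cfg.g,
        k=cfg.k,
        seed=cfg.seed,
        carriers=tuple(carriers),
        shared=intersect_all(all_segments),
    )
    return SimulatedCohort(
        config=cfg,
        truth=truth,
        sample_ids=sample_ids,
        positions=positions,
        ref_alleles=ref_alleles,
        alt_alleles=alt_alleles,
        genotypes=genotypes,
        depths=depths,
    )


# ---------------------------------------------------------------------------
# Trio-table fixture generator for the recessive filter
# ---------------------------------------------------------------------------

_VIOLATIONS = (
    "proband_hom_ref",
    "hom_parent_not_het",
    "het_without_partner",
    "hom_exac_over",
    "hom_kg_over",
)


def simulate_trio_table(
    n_background: int = 50,
    n_homozygous: int = 1,
    n_compound_het: int = 1,
    seed: int = 0,
) -> Tuple[List[AnnotatedVariant], Dict[str, list]]:
    """Generate an annotated trio variant table with implanted candidates.

    Exactly the implanted variants satisfy the recessive model with panel
    homozygote counts under the exclusion thresholds; every background row
    violates at least one rule. Returns ``(variants, truth)`` where truth
    lists the implanted homozygous variant keys and compound-het key pairs.
    """
    rng = np.random.default_rng(seed)
    variants: List[AnnotatedVariant] = []
    truth: Dict[str, list] = {"homozygous": [], "compound_het_pairs": []}
    gene_no = 0

    def _mk(gene: str, pos: int, proband, mother, father, exac: int, kg: int,
            cds: Optional[int] = None, prot: Optional[str] = None) -> AnnotatedVariant:
        ref, alt = (str(b) for b in rng.choice(_BASES, size=2, replace=False))
        return AnnotatedVariant(
            chrom=f"chr{int(rng.integers(1, 23))}",
            pos=pos,
            ref=ref,
            alt=alt,
            gene_id=gene,
            proband_gt=proband,
            mother_gt=mother,
            father_gt=father,
            exac_hom_count=exac,
            kg_hom_count=kg,
            cds_pos=cds,
            protein_change=prot,
        )

    for _ in range(n_homozygous):
        gene_no += 1
        v = _mk(
            f"GENE{gene_no:04d}",
            int(rng.integers(1_000, 50_000_000)),
            Genotype.HOM_ALT,
            Genotype.HET,
            Genotype.HET,
            int(rng.integers(0, 21)),
            int(rng.integers(0, 11)),
            cds=41,
            prot="p.Leu14Pro",
        )
        variants.append(v)
        truth["homozygous"].append(v.key)

    for _ in range(n_compound_het):
        gene_no += 1
        gene = f"GENE{gene_no:04d}"
        a = _mk(gene, int(rng.integers(1_000, 50_000_000)), Genotype.HET,
                Genotype.HET, Genotype.HOM_REF,
                int(rng.integers(0, 21)), int(rng.integers(0, 11)),
                cds=41, prot="p.Leu14Pro")
        b = _mk(gene, int(rng.integers(1_000, 50_000_000)), Genotype.HET,
                Genotype.HOM_REF, Genotype.HET,
                int(rng.integers(0, 21)), int(rng.integers(0, 11)),
                cds=481, prot="p.Arg161*")
        variants.extend([a, b])
        truth["compound_het_pairs"].append((a.key, b.key))

    for _ in range(n_background):
        gene_no += 1
        gene = f"GENE{gene_no:04d}"
        vtype = _VIOLATIONS[int(rng.integers(0, len(_VIOLATIONS)))]
        pos = int(rng.integers(1_000, 50_000_000))
        if vtype == "proband_hom_ref":
            v = _mk(gene, pos, Genotype.HOM_REF, Genotype.HET,
                    Genotype.HET, int(rng.integers(0, 21)), int(rng.integers(0, 11)))
        elif vtype == "hom_parent_not_het":
            mother = Genotype.HOM_REF if rng.random() < 0.5 else Genotype.HOM_ALT
            v = _mk(gene, pos, Genotype.HOM_ALT, mother, Genotype.HET,
                    int(rng.integers(0, 21)), int(rng.integers(0, 11)))
        elif vtype == "het_without_partner":
            v = _mk(gene, pos, Genotype.HET, Genotype.HET,
                    Genotype.HOM_REF, int(rng.integers(0, 21)), int(rng.integers(0, 11)))
        elif vtype == "hom_exac_over":
            v = _mk(gene, pos, Genotype.HOM_ALT, Genotype.HET,
                    Genotype.HET, int(rng.integers(21, 200)), int(rng.integers(0, 11)))
        else:  # hom_kg_over
            v = _mk(gene, pos, Genotype.HOM_ALT, Genotype.HET,
                    Genotype.HET, int(rng.integers(0, 21)), int(rng.integers(11, 100)))
        variants.append(v)
    return variants, truth


# ---------------------------------------------------------------------------
# Worked example: an engineered three-carrier cohort
# ---------------------------------------------------------------------------

WORKED_EXAMPLE_SAMPLES = ["case1", "case2", "case3"]
WORKED_EXAMPLE_INDEX = ("chr4", 122_722_620)

# (pos, ref, alt, gt1, gt2, gt3, depth) — depth applies to all samples.
_WORKED_EXAMPLE_ROWS = [
    (117_000_000, "A", "G", "0/0", "0/0", "0/0", 40),
    (117_649_359, "T", "A", "0/1", "0/0", "0/0", 40),
    (118_500_000, "A", "C", "1/1", "0/1", "0/0", 40),
    (122_000_000, "G", "T", "0/0", "0/0", "0/1", 40),
    (122_350_000, "C", "A", "0/0", "0/1", "0/0", 40),
    (122_400_000, "A", "C", "1/1", "1/1", "1/1", 40),
    (122_500_000, "T", "G", "1/1", "0/0", "1/1", 40),
    (122_600_000, "G", "A", "0/0", "0/1", "0/0", 5),  # low depth: filtered out
    (122_722_620, "T", "C", "1/1", "1/1", "1/1", 34),  # index variant
    (122_800_000, "AT", "A", "0/1", "0/1", "0/1", 40),  # indel: filtered out
    (122_900_000, "C", "T,G", "1/1", "2/2", "1/1", 40),  # hom for different alleles
    (123_000_000, "A", "G", "1/1", "1/1", "0/0", 40),
    (123_200_000, "G", "A", "1/1", "1/1", "1/1", 40),
    (123_250_000, "T", "C", "0/0", "0/0", "0/1", 40),
    (123_500_000, "A", "T", "1/1", "0/1", "0/0", 40),
    (131_644_866, "C", "G", "0/1", "0/0", "0/0", 40),
    (132_000_000, "T", "A", "0/0", "0/0", "0/0", 40),
]


def write_worked_example_vcf(path: str | os.PathLike) -> Dict[str, object]:
    """Write the packaged worked-example cohort: three carriers of chr4:122,722,620.

    A synthetic, fully deterministic three-sample VCF engineered so that the
    shared founder haplotype is exactly chr4:122,400,000-123,200,000
    (800 kb): case1 carries a ~14.0 Mb outer ROH, case2 and case3 ~1 Mb
    ROHs, and the shared homozygotes inside every outer region span exactly
    the 800 kb interval. A low-depth site and an indel are planted inside
    the region to exercise the high-confidence filter.

    Returns a small manifest (samples, chrom, index position).
    """
    chrom, index_pos = WORKED_EXAMPLE_INDEX
    lines = [
        "##fileformat=VCFv4.2",
        "##source=founderhap-worked-example",
        f"##contig=<ID={chrom},length=190214555>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(WORKED_EXAMPLE_SAMPLES),
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for pos, ref, alt, g1, g2, g3, dp in _WORKED_EXAMPLE_ROWS:
            fields = [chrom, str(pos), ".", ref, alt, ".", ".", ".", "GT:DP"]
            fields += [f"{g}:{dp}" for g in (g1, g2, g3)]
            fh.write("\t".join(fields) + "\n")
    return {
        "samples": list(WORKED_EXAMPLE_SAMPLES),
        "chrom": chrom,
        "index_pos": index_pos,
        "n_records": len(_WORKED_EXAMPLE_ROWS),
    }
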