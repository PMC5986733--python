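"""End-to-end drivers: configuration, report assembly, and file outputs.

Two pipelines share a single :class:`RunConfig`:

* :func:`run_share_pipeline` — VCF -> high-confidence tracks -> per-carrier
  ROH -> shared haplotype -> founder-age estimates (plus optional gene
  overlap from a BED file). Writes per-sample and shared BED, a filter
  tally TSV and a JSON report.
* :func:`run_filter_pipeline` — annotated trio TSV -> recessive-model
  candidates -> panel homozygote-count exclusion. Writes candidate and
  removal-log TSVs and a JSON report.

Reports embed the package version, the configuration echo and the seed, so
a run is reproducible from its own report; with a fixed seed the report
JSON is bit-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence

import yaml

from . import __version__
from .genmap import GeneticMap, read_genetic_map
from .intervals import GenomicInterval
from .model import FounderHaplotypeModel
from .recessive import (
    apply_recessive_model,
    panel_count_filter,
    read_variant_table,
    write_variant_table,
)
from .variant_io import read_bed, write_bed

logger = logging.getLogger("founderhap")

__all__ = ["RunConfig", "RunReport", "run_share_pipeline", "run_filter_pipeline"]


@dataclass
class RunConfig:
    """Declarative configuration for the pipelines (YAML-loadable)."""

    vcf: Optional[str] = None
    samples: List[str] = field(default_factory=list)
    index_chrom: str = ""
    index_pos: int = 0
    index_ref: Optional[str] = None
    index_alt: Optional[str] = None
    genetic_map: Optional[str] = None  # path to a tab-separated map
    cm_per_mb: float = 1.0
    gene_bed: Optional[str] = None
    variant_tsv: Optional[str] = None
    min_depth: int = 10
    exac_hom_max: int = 20
    kg_hom_max: int = 10
    lenient_parents: bool = False
    n_boot: int = 1000
    seed: int = 0
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("min_depth", "exac_hom_max", "kg_hom_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.cm_per_mb <= 0:
            raise ValueError("cm_per_mb must be positive")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike, **overrides) -> "RunConfig":
        """Load a config file; keyword overrides (e.g. CLI flags) win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s) in {path}: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def resolve_map(self) -> GeneticMap:
        if self.genetic_map:
            return read_genetic_map(self.genetic_map, chrom=self.index_chrom)
        return GeneticMap(chrom=self.index_chrom, rate_cm_per_mb=self.cm_per_mb)


@dataclass
class RunReport:
    """Serializable run record; round-trips losslessly through JSON."""

    kind: str  # "share" | "filter"
    version: str
    seed: int
    config: Dict
    share: Optional[Dict] = None
    filtering: Optional[Dict] = None

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent, sort_keys=True)

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(**json.loads(text))


def _gene_overlaps(bed_path: str, interval: GenomicInterval) -> List[Dict]:
    out = []
    for iv, name in read_bed(bed_path):
        hit = interval.intersect(iv)
        if hit is not None:
            out.append(
                {"gene": name or f"{iv.chrom}:{iv.start}-{iv.end}",
                 "start": iv.start, "end": iv.end,
                 "overlap_bp": hit.length_bp}
            )
    return out


def run_share_pipeline(config: RunConfig) -> RunReport:
    """Run VCF -> ROH -> shared haplotype -> founder age, with file outputs."""
    if not config.vcf:
        raise ValueError("share pipeline requires a VCF path")
    if len(config.samples) < 2:
        raise ValueError("share pipeline requires at least two carrier samples")
    if not config.index_chrom or config.index_pos < 1:
        raise ValueError("share pipeline requires an index variant (chrom, pos)")

    model = FounderHaplotypeModel.from_vcf(
        config.vcf,
        samples=config.samples,
        index_chrom=config.index_chrom,
        index_pos=config.index_pos,
        min_depth=config.min_depth,
        genetic_map=config.resolve_map(),
    )
    for t in model.tracks:
        logger.info(
            "sample %s: %d calls -> %d high-confidence markers (%s)",
            t.sample_id, t.filter_tally.get("input", len(t)), len(t),
            ", ".join(f"{k}={v}" for k, v in sorted(t.filter_tally.items()) if k.startswith("removed")),
        )
    results = model.fit(n_boot=config.n_boot, seed=config.seed)
    logger.info("shared haplotype %s (%s)", results.shared.interval, results.length_label)

    share: Dict = results.to_dict()
    share["filter_tallies"] = {t.sample_id: t.filter_tally for t in model.tracks}
    if config.gene_bed:
        share["gene_overlaps"] = _gene_overlaps(config.gene_bed, results.shared.interval)

    report = RunReport(
        kind="share",
        version=__version__,
        seed=config.seed,
        config=asdict(config),
        share=share,
    )

    if config.outdir:
        os.makedirs(config.outdir, exist_ok=True)
        write_bed(
            [r.outer for r in results.regions] + [r.trimmed for r in results.regions],
            os.path.join(config.outdir, "roh.bed"),
            names=[f"{r.sample_id}_outer" for r in results.regions]
            + [f"{r.sample_id}_trimmed" for r in results.regions],
        )
        write_bed(
            [results.shared.interval],
            os.path.join(config.outdir, "shared_haplotype.bed"),
            names=["shared_haplotype"],
        )
        with open(os.path.join(config.outdir, "filter_tally.tsv"), "w") as fh:
            fh.write("sample\tmetric\tcount\n")
            for t in model.tracks:
                for k, v in sorted(t.filter_tally.items()):
                    fh.write(f"{t.sample_id}\t{k}\t{v}\n")
        report.write(os.path.join(config.outdir, "share_report.json"))
    return report


def run_filter_pipeline(config: RunConfig) -> RunReport:
    """Run the recessive-model + panel-count filtering on an annotated trio TSV."""
    if not config.variant_tsv:
        raise ValueError("filter pipeline requires a variant TSV path")
    variants = read_variant_table(config.variant_tsv)
    after_model = apply_recessive_model(variants, lenient_parents=config.lenient_parents)
    candidates = panel_count_filter(
        after_model, exac_hom_max=config.exac_hom_max, kg_hom_max=config.kg_hom_max
    )

    tallies = {
        "input_variants": len(variants),
        "homozygous_candidates": len(candidates.homozygous),
        "compound_het_pairs": len(candidates.compound_het_pairs),
        "unresolved": len(candidates.unresolved),
        "removals_logged": len(candidates.log),
    }
    for key, count in sorted(tallies.items()):
        logger.info("filter tally %s=%d", key, count)

    filtering = {
        "tallies": tallies,
        "homozygous": [v.key for v in candidates.homozygous],
        "compound_het_pairs": [[a.key, b.key] for a, b in candidates.compound_het_pairs],
        "unresolved": [v.key for v in candidates.unresolved],
        "removal_log": [
            {"variant": e.variant_key, "stage": e.stage, "reason": e.reason}
            for e in candidates.log
        ],
    }
    report = RunReport(
        kind="filter",
        version=__version__,
        seed=config.seed,
        config=asdict(config),
        filtering=filtering,
    )
    if config.outdir:
        os.makedirs(config.outdir, exist_ok=True)
        write_variant_table(
            candidates.homozygous, os.path.join(config.outdir, "homozygous_candidates.tsv")
        )
        pair_rows = [v for pair in candidates.compound_het_pairs for v in pair]
        write_variant_table(
            pair_rows, os.path.join(config.outdir, "compound_het_candidates.tsv")
        )
        with open(os.path.join(config.outdir, "removal_log.tsv"), "w") as fh:
            fh.write("variant\tstage\treason\n")
            for e in candidates.log:
                fh.write(f"{e.variant_key}\t{e.stage}\t{e.reason}\n")
        report.write(os.path.join(config.outdir, "filter_report.json"))
    return report
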