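"""Recessive-model trio filtering with reference-panel homozygote exclusion.

Candidate variants for an autosomal-recessive condition are either

* **homozygous candidates** — homozygous-alt in the proband with both
  parents heterozygous (each parent demonstrably carries one copy), or
* **compound-heterozygous pairs** — two distinct heterozygous variants in
  the same gene, one inherited from each parent (a maternal-only het paired
  with a paternal-only het).

Surviving candidates are then screened against reference panels: a variant
is excluded if it has been seen homozygous more than ``exac_hom_max`` times
in ExAC (default 20) or more than ``kg_hom_max`` times in the 1000 Genomes
Project (default 10); both thresholds are exclusive, so counts of exactly
20 and 10 survive. Every removal is logged with a reason.

Small HGVS utilities map a coding-DNA position to its codon
(``codon = ceil(c.pos / 3)``) and cross-check the residue number embedded
in a ``p.`` protein change against it.
"""

from __future__ import annotations

import math
import os
import re
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .variant_io import Genotype

__all__ = [
    "AnnotatedVariant",
    "FilterLogEntry",
    "CandidateSet",
    "apply_recessive_model",
    "panel_count_filter",
    "cds_to_codon",
    "check_protein_consistency",
    "read_variant_table",
    "write_variant_table",
]

_GT_NAMES = {
    "hom_ref": Genotype.HOM_REF,
    "het": Genotype.HET,
    "hom_alt": Genotype.HOM_ALT,
    "missing": Genotype.MISSING,
}


@dataclass(frozen=True)
class AnnotatedVariant:
    """One annotated variant with trio genotypes and panel homozygote counts."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    proband_gt: Genotype
    mother_gt: Genotype
    father_gt: Genotype
    exac_hom_count: Optional[int]
    kg_hom_count: Optional[int]
    cds_pos: Optional[int] = None
    protein_change: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("exac_hom_count", "kg_hom_count"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.cds_pos is not None and self.cds_pos < 1:
            raise ValueError(f"cds_pos must be >= 1, got {self.cds_pos}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class FilterLogEntry:
    variant_key: str
    stage: str  # "recessive_model" | "panel_counts"
    reason: str


@dataclass
class CandidateSet:
    """Surviving candidates plus a full removal log."""

    homozygous: List[AnnotatedVariant] = field(default_factory=list)
    compound_het_pairs: List[Tuple[AnnotatedVariant, AnnotatedVariant]] = field(default_factory=list)
    unresolved: List[AnnotatedVariant] = field(default_factory=list)
    log: List[FilterLogEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in self.compound_het_pairs:
            if a.key == b.key:
                raise ValueError("compound-het pair members must differ")
            if a.gene_id != b.gene_id:
                raise ValueError("compound-het pair members must share a gene")

    @property
    def candidate_keys(self) -> set:
        keys = {v.key for v in self.homozygous}
        for a, b in self.compound_het_pairs:
            keys.update((a.key, b.key))
        return keys


def apply_recessive_model(
    variants: Sequence[AnnotatedVariant],
    lenient_parents: bool = False,
) -> CandidateSet:
    """Filter a trio variant table under an autosomal-recessive model.

    Strict mode requires both parents heterozygous for a homozygous
    candidate; with ``lenient_parents`` a parent merely needs not to be
    homozygous-alt (tolerates genotype dropout in a parent). Variants with
    a missing parental genotype that would otherwise qualify are set aside
    as "unresolved segregation" rather than silently promoted or dropped.
    """
    cs = CandidateSet()
    by_gene: Dict[str, Dict[str, List[AnnotatedVariant]]] = {}

    for v in variants:
        if v.proband_gt is Genotype.MISSING:
            cs.log.append(FilterLogEntry(v.key, "recessive_model", "proband genotype missing"))
            continue
        if v.proband_gt is Genotype.HOM_REF:
            cs.log.append(FilterLogEntry(v.key, "recessive_model", "proband homozygous reference"))
            continue

        parents_missing = (
            v.mother_gt is Genotype.MISSING or v.father_gt is Genotype.MISSING
        )
        if v.proband_gt is Genotype.HOM_ALT:
            if parents_missing:
                cs.unresolved.append(v)
                cs.log.append(
                    FilterLogEntry(v.key, "recessive_model", "unresolved: parental genotype missing")
                )
                continue
            if lenient_parents:
                ok = v.mother_gt is not Genotype.HOM_ALT and v.father_gt is not Genotype.HOM_ALT
            else:
                ok = v.mother_gt is Genotype.HET and v.father_gt is Genotype.HET
            if ok:
                cs.homozygous.append(v)
            else:
                cs.log.append(
                    FilterLogEntry(
                        v.key,
                        "recessive_model",
                        "homozygous in proband but parental genotypes inconsistent "
                        "with one transmitted allele each",
                    )
                )
            continue

        # proband het: classify by transmitting parent for compound-het pairing
        if parents_missing:
            cs.unresolved.append(v)
            cs.log.append(
                FilterLogEntry(v.key, "recessive_model", "unresolved: parental genotype missing")
            )
            continue
        maternal = v.mother_gt is Genotype.HET and v.father_gt is Genotype.HOM_REF
        paternal = v.father_gt is Genotype.HET and v.mother_gt is Genotype.HOM_REF
        slot = by_gene.setdefault(v.gene_id, {"maternal": [], "paternal": []})
        if maternal:
            slot["maternal"].append(v)
        elif paternal:
            slot["paternal"].append(v)
        else:
            cs.log.append(
                FilterLogEntry(
                    v.key,
                    "recessive_model",
                    "heterozygous in proband without an unambiguous single transmitting parent",
                )
            )

    for gene, slot in sorted(by_gene.items()):
        if slot["maternal"] and slot["paternal"]:
            for a in slot["maternal"]:
                for b in slot["paternal"]:
                    cs.compound_het_pairs.append((a, b))
        else:
            side = "maternal" if slot["maternal"] else "paternal"
            for v in slot["maternal"] + slot["paternal"]:
                cs.log.append(
                    FilterLogEntry(
                        v.key,
                        "recessive_model",
                        f"heterozygous ({side}) without a partner variant from the other parent "
                        f"in {gene}",
                    )
                )
    return cs


def _panel_keep(v: AnnotatedVariant, exac_hom_max: int, kg_hom_max: int) -> Tuple[bool, Optional[str]]:
    exac = 0 if v.exac_hom_count is None else v.exac_hom_count
    kg = 0 if v.kg_hom_count is None else v.kg_hom_count
    if exac < 0 or kg < 0:
        raise ValueError(f"negative panel homozygote count for {v.key}")
    if exac > exac_hom_max:
        return False, f"ExAC homozygote count {exac} > {exac_hom_max}"
    if kg > kg_hom_max:
        return False, f"1000 Genomes homozygote count {kg} > {kg_hom_max}"
    return True, None


def panel_count_filter(
    candidates: CandidateSet,
    exac_hom_max: int = 20,
    kg_hom_max: int = 10,
) -> CandidateSet:
    """Remove candidates seen too often homozygous in reference panels.

    A variant is removed iff its ExAC homozygote count exceeds
    ``exac_hom_max`` or its 1000 Genomes homozygote count exceeds
    ``kg_hom_max`` (both exclusive). A compound-het pair is removed when
    either member is removed. Missing counts are treated as 0 and logged.
    """
    out = CandidateSet(log=list(candidates.log))

    def _note_missing(v: AnnotatedVariant) -> None:
        if v.exac_hom_count is None or v.kg_hom_count is None:
            out.log.append(
                FilterLogEntry(v.key, "panel_counts", "missing panel count treated as 0")
            )

    for v in candidates.homozygous:
        _note_missing(v)
        keep, reason = _panel_keep(v, exac_hom_max, kg_hom_max)
        if keep:
            out.homozygous.append(v)
        else:
            out.log.append(FilterLogEntry(v.key, "panel_counts", reason))
    for a, b in candidates.compound_het_pairs:
        _note_missing(a)
        _note_missing(b)
        keep_a, reason_a = _panel_keep(a, exac_hom_max, kg_hom_max)
        keep_b, reason_b = _panel_keep(b, exac_hom_max, kg_hom_max)
        if keep_a and keep_b:
            out.compound_het_pairs.append((a, b))
        else:
            bad = a.key if not keep_a else b.key
            reason = reason_a if not keep_a else reason_b
            out.log.append(
                FilterLogEntry(bad, "panel_counts", f"pair removed: {reason}")
            )
    for v in candidates.unresolved:
        _note_missing(v)
        keep, reason = _panel_keep(v, exac_hom_max, kg_hom_max)
        if keep:
            out.unresolved.append(v)
        else:
            out.log.append(FilterLogEntry(v.key, "panel_counts", reason))
    return out


def cds_to_codon(cds_pos: int) -> Tuple[int, int]:
    """Codon number and within-codon offset (1-3) of a coding-DNA position.

    c.41 falls in codon 14 (offset 2); c.481 starts codon 161 (offset 1).
    """
    if cds_pos < 1:
        raise ValueError(f"cds position must be >= 1, got {cds_pos}")
    return math.ceil(cds_pos / 3), (cds_pos - 1) % 3 + 1


_HGVS_P = re.compile(
    r"^p\.\(?(?:[A-Z][a-z]{2}|[A-Z])(\d+)(?:[A-Z][a-z]{2}|[A-Z]|\*|Ter|=)?\)?$"
)


def check_protein_consistency(variant: AnnotatedVariant) -> Tuple[bool, str]:
    """Check that the residue number in ``protein_change`` matches the cds position.

    Handles simple HGVS substitutions and stop gains (p.Leu14Pro,
    p.Arg161*). Returns ``(passed, message)``; an unparseable string fails
    with a message rather than raising.
    """
    if variant.cds_pos is None or not variant.protein_change:
        return False, f"{variant.key}: cds position or protein change absent"
    m = _HGVS_P.match(variant.protein_change.strip())
    if not m:
        return False, f"{variant.key}: cannot parse HGVS protein change {variant.protein_change!r}"
    residue = int(m.group(1))
    codon, _ = cds_to_codon(variant.cds_pos)
    if residue == codon:
        return True, (
            f"{variant.key}: c.{variant.cds_pos} lies in codon {codon}, "
            f"consistent with {variant.protein_change}"
        )
    return False, (
        f"{variant.key}: c.{variant.cds_pos} lies in codon {codon} but "
        f"{variant.protein_change} names residue {residue}"
    )


# ---------------------------------------------------------------------------
# TSV interchange
# ---------------------------------------------------------------------------

_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "proband_gt", "mother_gt",
    "father_gt", "exac_hom", "kg_hom", "cds_pos", "protein_change",
]


def read_variant_table(path: str | os.PathLike) -> List[AnnotatedVariant]:
    """Read an annotated trio variant table (TSV with named columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _COLUMNS[:10] if c not in df.columns]
    if missing:
        raise ValueError(f"variant table {path} lacks required column(s): {missing}")
    bad_rows = []
    out = []
    for i, row in df.iterrows():
        try:
            gts = {}
            for col in ("proband_gt", "mother_gt", "father_gt"):
                raw = str(row[col]).strip().lower()
                if raw in ("nan", "", "."):
                    raw = "missing"
                gts[col] = _GT_NAMES[raw]
            out.append(
                AnnotatedVariant(
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    ref=str(row["ref"]),
                    alt=str(row["alt"]),
                    gene_id=str(row["gene"]),
                    proband_gt=gts["proband_gt"],
                    mother_gt=gts["mother_gt"],
                    father_gt=gts["father_gt"],
                    exac_hom_count=None if pd.isna(row["exac_hom"]) else int(row["exac_hom"]),
                    kg_hom_count=None if pd.isna(row["kg_hom"]) else int(row["kg_hom"]),
                    cds_pos=None
                    if "cds_pos" not in df.columns or pd.isna(row.get("cds_pos"))
                    else int(row["cds_pos"]),
                    protein_change=None
                    if "protein_change" not in df.columns or pd.isna(row.get("protein_change"))
                    else str(row["protein_change"]),
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            bad_rows.append(f"row {i}: {exc}")
    if bad_rows:
        raise ValueError(f"malformed variant table {path}: " + "; ".join(bad_rows))
    return out


def write_variant_table(variants: Sequence[AnnotatedVariant], path: str | os.PathLike) -> None:
    rows = []
    for v in variants:
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene_id,
                "proband_gt": v.proband_gt.name.lower(),
                "mother_gt": v.mother_gt.name.lower(),
                "father_gt": v.father_gt.name.lower(),
                "exac_hom": v.exac_hom_count,
                "kg_hom": v.kg_hom_count,
                "cds_pos": v.cds_pos,
                "protein_change": v.protein_change,
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)
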