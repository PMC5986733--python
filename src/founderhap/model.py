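"""Model/Results interface for founder-haplotype dating.

:class:`FounderHaplotypeModel` is built from carrier marker tracks around
a known index variant (typically via :meth:`FounderHaplotypeModel.from_vcf`);
``fit()`` runs the extend-trim-intersect procedure and the age estimators
and returns a :class:`FounderHaplotypeResults` carrying the per-carrier
ROH regions, the shared haplotype, its physical and genetic lengths, both
generation estimates with bootstrap confidence intervals, and a
``summary()`` table. Plotting of the per-carrier regions hangs off the
results object.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from . import age as _age
from .genmap import GeneticMap, physical_to_genetic
from .intervals import GenomicInterval, format_length, interval_length
from .roh import ROHRegion, SharedHaplotype, delimit_roh, intersect_regions
from .variant_io import Genotype, MarkerTrack, load_marker_tracks

__all__ = ["FounderHaplotypeModel", "FounderHaplotypeResults"]


class FounderHaplotypeModel:
    """Founder-haplotype dating model for a set of homozygous carriers.

    Parameters
    ----------
    tracks
        High-confidence marker tracks, one per carrier, all on the
        chromosome of the index variant. At least two carriers are
        required, and every carrier must be homozygous non-reference at
        ``index_pos``.
    index_pos
        1-based position of the index (disease) variant.
    genetic_map
        Physical-to-genetic conversion; defaults to a uniform 1 cM/Mb map.
    """

    def __init__(
        self,
        tracks: Sequence[MarkerTrack],
        index_pos: int,
        genetic_map: Optional[GeneticMap] = None,
    ) -> None:
        if len(tracks) < 2:
            raise ValueError("founder-haplotype dating needs at least two carriers")
        chroms = {t.chrom for t in tracks}
        if len(chroms) > 1:
            raise ValueError(f"carrier tracks span multiple chromosomes: {sorted(chroms)}")
        for t in tracks:
            gt = t.genotype_at(index_pos)
            if gt is None:
                raise ValueError(
                    f"carrier {t.sample_id} has no high-confidence call at the "
                    f"index position {index_pos}"
                )
            if gt is not Genotype.HOM_ALT:
                raise ValueError(
                    f"carrier {t.sample_id} is {gt.name} (not homozygous "
                    f"non-reference) at the index position {index_pos}"
                )
        self.tracks = list(tracks)
        self.index_pos = int(index_pos)
        self.chrom = tracks[0].chrom
        self.genetic_map = genetic_map if genetic_map is not None else GeneticMap(chrom=self.chrom)

    @classmethod
    def from_vcf(
        cls,
        path: str | os.PathLike,
        samples: Sequence[str],
        index_chrom: str,
        index_pos: int,
        min_depth: int = 10,
        genetic_map: Optional[GeneticMap] = None,
    ) -> "FounderHaplotypeModel":
        """Build the model straight from a multi-sample VCF."""
        tracks = load_marker_tracks(path, samples=samples, chrom=index_chrom, min_depth=min_depth)
        return cls(tracks, index_pos, genetic_map=genetic_map)

    def fit(self, n_boot: int = 1000, seed: int = 0) -> "FounderHaplotypeResults":
        """Delimit, trim and intersect the carrier ROHs, then date the founder."""
        regions = [delimit_roh(t, self.tracks, self.index_pos) for t in self.tracks]
        shared = intersect_regions(regions, tracks=self.tracks)
        length_bp = interval_length(shared.interval)
        length_cm = physical_to_genetic(shared.interval, self.genetic_map)
        if length_cm <= 0:
            raise ValueError(
                "shared haplotype has zero genetic length; dating is undefined "
                "(degenerate single-marker haplotype?)"
            )
        k = len(self.tracks)
        age_length = _age.mc_confidence(
            length_cm, k=1, method=_age.AgeMethod.LENGTH_APPROXIMATION,
            n_sims=n_boot, seed=seed,
        )
        age_model = _age.mc_confidence(
            length_cm, k=k, method=_age.AgeMethod.MODEL_INVERSION,
            n_sims=n_boot, seed=seed,
        )
        return FounderHaplotypeResults(
            model=self,
            regions=regions,
            shared=shared,
            length_bp=length_bp,
            length_cm=length_cm,
            age_length=age_length,
            age_model=age_model,
            n_boot=n_boot,
            seed=seed,
        )


@dataclass
class FounderHaplotypeResults:
    """Fitted founder-haplotype analysis: intervals, lengths, and age estimates."""

    model: FounderHaplotypeModel
    regions: List[ROHRegion]
    shared: SharedHaplotype
    length_bp: int
    length_cm: float
    age_length: _age.AgeEstimate  # g = 100 / L_cM
    age_model: _age.AgeEstimate  # g = 100 / (k L_cM)
    n_boot: int
    seed: int

    @property
    def length_label(self) -> str:
        return format_length(self.length_bp)

    def to_dict(self) -> Dict:
        def _iv(iv: GenomicInterval) -> Dict:
            return {"chrom": iv.chrom, "start": iv.start, "end": iv.end}

        def _est(e: _age.AgeEstimate) -> Dict:
            return {
                "g_point": e.g_point,
                "method": e.method.value,
                "k": e.k,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "ci_level": e.ci_level,
                "n_sims": e.n_sims,
                "seed": e.seed,
                "warnings": list(e.warnings),
            }

        return {
            "index": {"chrom": self.model.chrom, "pos": self.model.index_pos},
            "carriers": [
                {
                    "sample_id": r.sample_id,
                    "outer": _iv(r.outer),
                    "trimmed": _iv(r.trimmed),
                    "outer_length_bp": interval_length(r.outer),
                    "left_het_pos": r.left_het_pos,
                    "right_het_pos": r.right_het_pos,
                    "left_shared_hom_pos": r.left_shared_hom_pos,
                    "right_shared_hom_pos": r.right_shared_hom_pos,
                    "degenerate": r.degenerate,
                }
                for r in self.regions
            ],
            "shared_haplotype": {
                "interval": _iv(self.shared.interval),
                "sample_ids": list(self.shared.sample_ids),
                "n_shared_hom_support": self.shared.n_shared_hom_support,
                "length_bp": self.length_bp,
                "length_label": self.length_label,
                "length_cm": self.length_cm,
            },
            "age_estimates": {
                "length_approximation": _est(self.age_length),
                "model_inversion": _est(self.age_model),
            },
        }

    def summary(self) -> str:
        """Human-readable summary table of the fitted analysis."""
        lines = []
        w = 78
        lines.append("Founder-Haplotype Dating Results".center(w))
        lines.append("=" * w)
        lines.append(
            f"Index variant: {self.model.chrom}:{self.model.index_pos:,}    "
            f"Carriers: {len(self.regions)}"
        )
        lines.append("-" * w)
        lines.append(f"{'carrier':<12}{'outer ROH':>30}{'trimmed ROH':>30}")
        for r in self.regions:
            flag = " *" if r.degenerate else ""
            lines.append(
                f"{r.sample_id:<12}{str(r.outer):>30}{str(r.trimmed):>30}{flag}"
            )
        if any(r.degenerate for r in self.regions):
            lines.append("  * degenerate: no shared homozygote besides the index variant")
        lines.append("-" * w)
        lines.append(
            f"Shared haplotype: {self.shared.interval}  "
            f"({self.length_label}; {self.length_cm:.3f} cM; "
            f"{self.shared.n_shared_hom_support} supporting shared homozygotes)"
        )
        for label, e in (
            ("g (length approximation, 100/L)", self.age_length),
            (f"g (model inversion, 100/(kL), k={self.age_model.k})", self.age_model),
        ):
            ci = ""
            if e.ci_low is not None:
                ci = f"   [{100 * e.ci_level:.0f}% CI {e.ci_low:.1f} - {e.ci_high:.1f}]"
            lines.append(f"{label}: {e.g_point:.1f} generations{ci}")
        lines.append("=" * w)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot per-carrier outer/trimmed ROH intervals and the shared haplotype."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 1.0 + 0.6 * len(self.regions)))
        for y, r in enumerate(self.regions):
            ax.hlines(y, r.outer.start, r.outer.end, color="lightsteelblue", lw=6,
                      label="outer ROH" if y == 0 else None)
            ax.hlines(y, r.trimmed.start, r.trimmed.end, color="steelblue", lw=6,
                      label="trimmed ROH" if y == 0 else None)
        iv = self.shared.interval
        ax.axvspan(iv.start, iv.end, color="indianred", alpha=0.25, label="shared haplotype")
        ax.axvline(self.model.index_pos, color="k", ls="--", lw=1, label="index variant")
        ax.set_yticks(range(len(self.regions)))
        ax.set_yticklabels([r.sample_id for r in self.regions])
        ax.set_xlabel(f"position on {self.model.chrom} (bp)")
        ax.legend(loc="upper right", fontsize="small")
        return ax
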