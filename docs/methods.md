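# Methods

`founderhap` implements the haplotype side of a recessive disease-gene
study: given several unrelated individuals homozygous for the same rare
variant, it asks how large the chromosomal segment is that they all
inherited from a common founder, and how long ago that founder lived. It
also implements the variant-filtering step that nominates such a variant
from trio exomes in the first place, and a simulator that generates
cohorts of this structure with known truth.

## ROH delimitation and the shared haplotype

The unit of evidence is the **high-confidence marker track**: one sample's
calls on one chromosome reduced to non-indel SNVs with a called genotype
and read depth ≥ `min_depth` (default 10×). Indels and low-depth sites
are the dominant sources of spurious heterozygote calls in exome data, and
a single false het truncates a run of homozygosity (ROH), so the filter is
applied before any boundary is read off.

For each carrier the ROH around the index variant is *extended* outward
until the first high-confidence heterozygote on each side. Three
conventions matter and are fixed:

* the boundary sits one basepair inside the flanking het (the het itself
  is excluded), so endpoints are evidence-anchored and reproducible;
* homozygous-reference calls do not break a run — autozygosity is about
  zygosity, not alt-allele status — and filtered/missing sites are
  invisible to the scan;
* when no flanking het exists the boundary clips at the first/last marker
  of the track, not the chromosome end: there is no evidence beyond the
  markers, and the region is flagged as clipped.

Each outer region is then *trimmed* back to the outermost **shared
homozygotes** inside it — positions where every carrier is homozygous for
the identical non-reference allele. Sharing is defined on the allele, not
just the zygosity: at a multi-allelic site two carriers homozygous for
different alternates do not share. A site missing from any carrier's track
cannot be shared. If no shared homozygote other than the index variant
exists, the trimmed region degenerates to the single-point interval at the
index and is flagged. Finally the trimmed regions are *intersected*
(max-of-starts, min-of-ends); since every trimmed region contains the
index position the intersection is never empty. The trim already uses all
carriers, which makes the final intersection partially redundant; both
steps are nevertheless performed as separate, individually testable
operations, and the per-carrier trimmed regions are reported.

Interval lengths are quoted as `end − start`, the difference of the
coordinate pair, which is how region sizes are conventionally reported
(an 800,000 bp difference prints as "800 kb"); the 1 bp discrepancy with
an inclusive marker count is immaterial at these scales. Mb/kb renderings
round half-up (13,995,505 bp → "14.0 Mb"). Internally all coordinates are
1-based inclusive (VCF convention); BED output shifts to 0-based half-open
at the I/O boundary and round-trips exactly.

## Founder dating

Physical length converts to genetic length either through a user-supplied
recombination map (linear interpolation between knots; extrapolation
outside the map range is refused rather than guessed) or a uniform rate,
1 cM/Mb by default.

Two estimators of g, the number of generations from the founder to each
present-day carrier, are reported side by side:

* **length approximation**: g = 100 / L_cM. This is the classical
  two-haplotype result — a segment shared identically by descent through
  two lineages of g meioses each has expected length 2/(2g) Morgans — and
  is the headline number: 0.8 cM → 125 generations.
* **model inversion**: g = 100 / (k · L_cM) for k homozygous carriers.
  The shared interval is the intersection of 2k independently eroded
  segments; under Haldane's no-interference model each side of it is the
  minimum of 2k Exponential(g) extents, i.e. Exponential(2kg), so the
  expected total length is 1/(kg) Morgans. At k = 1 this reduces exactly
  to the length approximation. For three carriers it is k times smaller
  than the headline number and is always labelled, never silently
  substituted.

Both are method-of-moments inversions of a single observation, and the
observation is heavy-tailed: L ~ Gamma(shape 2, rate 2kg), so 1/L has
median 2kg/1.678. Consequently the point estimate overshoots the truth by
a factor 2/1.678 ≈ 1.19 *in median* (and by 2 in expectation). This bias
is inherent to inverting one segment length; an explicitly labelled
median-unbiased variant (`median_unbiased=True`, multiplying by
median(Gamma(2,1))/2 ≈ 0.839) is provided for simulation work, while the
default keeps the plain inversion that reproduces the conventional
125-generation figure.

**Uncertainty.** `mc_confidence` attaches a parametric-bootstrap interval:
at the point estimate ĝ it simulates shared lengths from the Gamma segment
model, re-applies the estimator, and takes the 2.5/97.5 percentiles of the
bootstrap estimates. Because ĝ is a pure scale statistic here, the ratio
ĝ*/ĝ is an *exact* pivot for ĝ/g, and the default interval maps the
bootstrap percentiles through it ([ĝ²/q₉₇.₅, ĝ²/q₂.₅]), giving essentially
exact 95% coverage. The naive percentile interval ([q₂.₅, q₉₇.₅]) is
retained as an option but is anti-conservative for this skewed one-
observation problem (analytically ≈ 84% coverage at nominal 95%). Note
that the interval's *relative* width does not shrink with k: a single
segment length is one observation regardless of how many carriers defined
it, and the estimator is scale-equivariant in k.

## Recessive trio filtering

Candidates are (a) proband homozygous-alt with both parents heterozygous
(strict; a `lenient_parents` flag relaxes this to "neither parent
homozygous-alt" for cohorts with parental dropout), or (b) gene-level
compound-heterozygous pairs formed by crossing maternal-only hets
(mother het, father hom-ref) with paternal-only hets — a pair can never
draw both variants through the same parent. Variants with a missing
parental genotype are parked in an "unresolved segregation" bucket rather
than silently promoted or dropped. Candidates are then removed if seen
homozygous more than 20 times in ExAC or more than 10 times in 1000
Genomes; both thresholds are exclusive (counts of exactly 20/10 survive),
missing counts are treated as 0 and logged, and every removal carries a
reason, so removal reasons partition the removed set. Only autosomal
inheritance is modelled. HGVS utilities cover the simple forms needed
here: codon = ⌈c.pos/3⌉ (c.41 → codon 14, c.481 → codon 161) and
consistency checking of `p.Xxx123Yyy` / `p.Xxx123*` substitutions.

## The simulator, and what passing tests do and don't show

`simulate_cohort` emulates the *structure* of the study data — k carriers
homozygous for a founder allele at an index position, genotyped
exome-style — not human genetics in general. Per lineage, segment extents
are Exponential(g) per side (Haldane, no interference); lineages are
independent (no inbreeding loops beyond the shared founder), which is
exactly the assumption the dating formulas make, so the simulator doubles
as their closed-form oracle. Markers arrive by Poisson process; background
alternate-allele frequencies are Beta(2, 5) truncated to [0.05, 0.5] so
heterozygotes are frequent enough to delimit ROH sharply; genotyping
errors flip to each other genotype with equal probability; depth is
Poisson and independent of genotype, with depth 0 emitted as a missing
call.

Defaults are the study conditions: g = 125, k = 3, index at
chr4:122,722,620 on a 190 Mb chromosome, 12 markers/Mb (the density of
high-confidence exome SNVs), error rate 0.002, mean depth 40×. The
recovery and convergence tests instead use a 40 Mb chromosome centred on
the index with g = 50 and densities of 400–500 markers/Mb so that marker
spacing is small relative to the segment scale; sizes (200 replicates for
recovery, 5,000 draws per cell of the g × k calibration grid, 500
replicates for CI coverage) were chosen to keep Monte-Carlo error well
below the tolerances being asserted.

What the simulator does *not* model: linkage disequilibrium and realistic
allele-frequency spectra, interference (crossover positions are
memoryless), population growth or inbreeding, depth–genotype coupling
(e.g. allelic dropout), and indels (the filter's indel handling is
exercised by explicit fixtures instead). Passing recovery tests therefore
demonstrate correctness of the algorithms and internal consistency of the
model, not robustness of the dating to violations of these assumptions —
on real data the dominant unmodelled uncertainties are the local
recombination rate and the single-observation variance discussed above.

`simulate_trio_table` constructs annotated trio tables in which exactly
the implanted variants satisfy the recessive model and panel thresholds,
and every background row violates at least one rule, giving the filter a
fixture with a known answer. All generator outputs are byte-reproducible
from (config, seed).

## Numerical and degenerate-input choices

* Duplicate positions after filtering (split multi-allelic records): first
  record wins, counted in the filter tally.
* Half-calls (`./1`) and any genotype containing a missing allele are
  treated as missing (conservative).
* Per-sample FORMAT/DP is preferred; site INFO/DP is the fallback and is
  flagged on the call; absent depth is 0 (and thus filtered).
* A degenerate single-marker shared haplotype has zero genetic length;
  dating refuses it with an explicit error rather than returning infinity.
* Genetic maps with zero-recombination plateaus have a set-valued inverse;
  the leftmost physical position is returned.
* Bootstrap intervals are clamped to bracket the point estimate (relevant
  only for pathological bootstrap draws at tiny `n_sims`).

## Worked-example fixture

The packaged three-carrier VCF (`write_worked_example_vcf`) is synthetic
and deterministic: one carrier has a ~14.0 Mb outer ROH
(chr4:117,649,360–131,644,865), the other two ~1 Mb ROHs, and the shared
homozygotes inside every outer region span exactly
chr4:122,400,000–123,200,000, so the pipeline reports an 800 kb shared
haplotype and 125 generations at 1 cM/Mb. A low-depth site and an indel
are planted inside the region to show that the high-confidence filter is
load-bearing: counted naively, either would split a carrier's ROH.
`scripts/acceptance.py` regenerates this cohort and recomputes the
pipeline end-to-end.
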