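# Methods

This note documents the models, parameter choices and numerical decisions
behind `tadevol`, and what the synthetic study does and does not establish
about real data.

## Insulation score and boundary calling

The per-bin TAD-separation score follows the standard multi-window diamond
construction: for window size *w* bins, the diamond mean at bin *i* averages
the contact counts over pairs (a, b) with i−w ≤ a < i ≤ b < i+w — exactly the
contacts that must cross bin *i*. Windows sweep `min_depth` = 100 Kb to
`max_depth` = 600 Kb in 50 Kb steps (11 windows at 10 Kb bins). The 50 Kb
step is a package choice: it brackets the depth range densely at negligible
cost. Diamond means are `log1p`-transformed before z-scoring because Hi-C
counts are heavy-tailed; the score is the mean z across windows, and is
defined only where every window fits inside the matrix (within `max_depth`
of a chromosome end the score is missing). A per-window standard deviation
at float-rounding scale (≤ 1e−8 relative) is treated as zero so that a
constant matrix scores exactly 0 instead of z-magnified arithmetic noise.

Boundary candidates are local minima with prominence ≥ `min_delta` = 0.01
below the lower of their two flanking local maxima (the edge of the defined
region acts as a flank). Significance: the candidate's smallest-window
crossing diamond is compared against the two flanking within-domain
triangles with a one-sided Wilcoxon rank-sum test, computed on
**distance-normalised** counts (each cell divided by its diagonal's
chromosome-wide mean). Raw counts would bias the test — within-domain cells
sit closer to the diagonal and are systematically larger under pure distance
decay — so O/E normalisation is what makes the test's null honest; this was
the single most consequential numerical decision in the module. P-values are
Benjamini–Hochberg adjusted across candidates (q ≤ 0.05 kept) and calls
closer than `min_depth` collapse to the lower-scoring one. The boundary
interval is the single minimum bin. `min_delta` and the q threshold are
exposed as flags; they stand in for tool-internal thresholds that are not
published.

Pileups report the anchor-averaged observed/expected submatrix (expected =
per-diagonal chromosome mean) and the per-offset median insulation score.
The default flank is 1 Mb (a 2 Mb window); the flank is a parameter since
breakpoint visualisations commonly use tighter windows.

## Synthetic study generator

The generator is first-class, tested code whose defaults *are* the study
conditions.

**Phylogeny.** Eight taxa in two clades of four —
(((human,(nomascus,hylobates)),rhesus),((mouse,(caroli,pahari)),rat)) — with
ultrametric branch lengths normalised to root-to-tip depth 1 and reference
taxa human and mouse. Branch lengths are configurable; the shipped shape
gives each clade one distant outgroup-like tip and a close pair, matching
the study design's mix of divergences.

**Boundary turnover.** Boundaries evolve by per-branch exponential loss
(rate λ per unit time) and Poisson gain (rate per bp per unit time, placed
uniformly subject to spacing). Lineage identity is tracked through the tree,
so true presence/absence — and therefore the true conservation label — is
exact, and liftover/merging/classification errors downstream are measurable
against it. Defaults: 80 root boundaries on a 60 Mb chromosome,
λ = 0.42, gain 4.9e−7 /bp/time, minimum spacing 120 Kb. The turnover rates
are not empirical estimates (none are published); they were calibrated once
so the union table has a study-like composition — about 15 % ultraconserved
and 15 % reference-specific among the reference species' boundaries — and
frozen. Spacing of 120 Kb reflects that TADs occupy at least ~100 Kb and
keeps distinct boundaries resolvable at the 100 Kb calling depth. Boundary
strength (the cross-boundary attenuation multiplier, lower = stronger
insulation) is drawn per lineage: ancestral lineages U(0.10, 0.20), gained
lineages U(0.20, 0.35), echoing the empirical pattern that older boundaries
insulate more strongly. All randomness flows from one seed through named
substreams, so runs are byte-reproducible.

**Contact matrices.** Expected counts are A·(j−i)^(−α) with α = 1, A = 100
at 10 Kb bins, times the product of strengths of boundaries strictly between
the bins; the diagonal is A; Poisson sampling adds noise. This emulates
distance decay plus boundary insulation only — no compartments, loops,
coverage or mappability bias, and no sequence. Consequently, passing
recovery tests show the *pipeline logic* is correct under its own model;
they do not certify performance on real Hi-C artefacts.

**Rearrangement.** Inversions and translocations are applied to a segment
list; the resulting coordinate map is exactly bijective, and true
breakpoints are the non-collinear block junctions of the derived genome.
Simulated maps are gap-free, so synteny chaining over them should use
`max_gap = 0`; the permissive 1 Mb default exists for alignment-block inputs
with scattered gaps, and would chain across small-displacement
translocations in an exact map.

**Annotations.** CTCF peaks are planted in boundaries with probability 0.5
(under half of real boundaries carry CTCF) plus a uniform background; an old
SINE family (MIR) is planted at CTCF sites in ultraconserved boundaries and
a young LTR family (ERV-K) at species-specific ones, with configurable
planting probabilities (0 = null). Case/control deletion CNVs hit
species-specific boundaries with per-cohort probabilities defaulting to the
published recurrence (335/1130 and 161/1130). The GC track is a smoothed
Gaussian field around 41 %; chromatin states are an exponential-length
random partition. These layers carry the planted associations and nothing
else — no sequence composition, motif structure or real repeat biology.

## Conservation

Liftover maps each interval base-wise through the coordinate map; an
interval lifts iff ≥ `min_match` = 0.95 of its bases (the UCSC liftOver
default) land in a single collinear run (one chain), and the lifted interval
is the span of those bases. Failures are reported, never dropped silently.

Union construction uses single-linkage chaining with an end-to-start gap
≤ 10 Kb (bedtools-merge semantics): transitivity is deliberate, so a chain
may span more than 10 Kb end-to-end, and each source boundary joins exactly
one chain. "Conserved within an order" is read strictly (all members of the
clade, none of the other); a loose ≥ 2-of-clade variant is available via
`strict_order_conservation=False`. Species-specific labels can be demoted to
`other` by outgroup exclusion sets (boundaries within the merge distance of,
e.g., chimpanzee/gorilla boundaries). Group shares are reported relative to
the rows containing the reference species; the table also supports the
union-row denominator, since the two differ and both appear in published
summaries.

Group comparisons use two-sided Wilcoxon rank-sum tests (reported as the
Mann–Whitney U, matching R's `wilcox.test` W). The gene-matched permutation
test draws, per permutation, a random boundary set matching the group's size
and gene-overlap count and compares median insulation, with
p = (1 + #{perm ≤ obs}) / (n_perm + 1).

## Synteny breakpoints

Chaining partitions src-sorted blocks into maximal runs whose consecutive
pairs are collinear (same chromosomes, same strand, order-consistent,
src and dst gaps in [0, max_gap]); runs containing at least one seed (length
> 1 Kb and score ≥ 100 000) are emitted. BOS are the 1 Kb flanks of each
elongated block on the rearranged genome, clipped at position 0 and, when
chromosome lengths are supplied, at the end; an unrearranged map therefore
yields no interior BOS. The duplication rule is inclusive (second hit
≥ 0.9 × top removes — conservative curation; flag to flip) and zero-hit
regions are removed as unmappable; the manual segmental-duplication step is
mechanised as an optional repeat-mask filter. GC-stratified sampling bins
observed BOS into ≤ 10 GC-quantile strata (duplicate quantile edges merge,
so a uniform-GC genome degenerates gracefully to uniform placement) and
draws matching per-stratum counts from the track's windows. The
conservation-composition permutation reports plain-proportion one-tailed
p-values out of n_perm = 100 on both sides (so p_over + p_under ≥ 1), with
the (k+1)/(n+1) estimator behind a flag and a resolution note when a count
is zero.

## Enrichment

The TE test labels each boundary-overlapping CTCF peak by the TE with the
largest overlap (ties to the earliest interval) and compares the per-unit
count against n_peaks × (unit coverage / genome size) with a two-sided exact
binomial (tail doubling). The exact binomial is the primary test; a
beta-binomial variant with an overdispersion parameter is available for
sensitivity analysis where counts are over-dispersed. A shuffle-based
expectation is out of scope; coverage fractions are the expectation model.
No multiple-testing correction is applied by default (matching the source
analyses' reporting convention); BH is a flag. Null calibration of the
binomial holds in an adequate-count regime (family coverage ~0.5–3 %,
hundreds of peaks); with expected counts ≪ 1 the exact test is conservative,
as exact tests are. The CNV recurrence test scores a boundary deleted in a
cohort iff ≥ 1 deletion overlaps it and applies Fisher's exact test over the
same boundary denominator in both cohorts.

## Problem sizes and scoring conventions

Recovery metrics score only boundaries in the callable interior (further
than `max_depth` from a chromosome end), because no method can call a
boundary where the score is undefined; on real chromosomes (≫ 60 Mb) the
edge zone is negligible, on toy chromosomes it is not. The shipped
full-scale study uses one 60 Mb chromosome per taxon; the demo runs the same
chain at 20 Mb with 30 root boundaries, preserving the gains-per-root-
boundary ratio so group proportions carry over. Tests that need Monte-Carlo
calibration (null rejection rates, survival closed form) use 200 replicates.

## Known limitations

Single-resolution, single-chromosome matrices; no TAD nesting, loops or
compartments; no tissue effects (the real cross-species comparison mixes
cell types); rearrangement classes are not inferred from data, only planted;
the liftover model has no paralogy — duplication ambiguity enters only
through the BOS hit-table filter; and all statistical calibration statements
are with respect to the generator's null, not real-genome nulls.
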