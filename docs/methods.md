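# Methods

## Coordinate conventions

All internal coordinates are 0-based, half-open `[start, end)`; GFF3 input
(1-based, inclusive) is converted on read, BED is taken as-is. The 3′ anchor
of a feature is `end` on the + strand and `start` on the − strand, i.e. the
half-open boundary just past the last transcribed base, so the first
downstream 25 bp bin covers `[anchor, anchor+25)` (+ strand) or
`[anchor−25, anchor)` (− strand). Windows are always reported in
transcription-direction offsets; this makes every downstream computation
exactly strand symmetric (verified by reflection tests).

"Downstream neighbor" means the nearest transcript *on the same strand*
whose 5′ start lies at or past the anchor; a neighbor spanning the anchor
has distance 0. Same-strand scope is the default because the tiling data
are strand separated, so readthrough signal can only collide with
same-strand annotation; `both_strands` is available for single-stranded
designs.

## Readthrough calling

Parameters (defaults): bin width 25 bp, window 150 bp = 6 bins, call
threshold >0.6 log2 per bin (strict), ≥4 of 6 bins (non-strict), neighbor
exclusion <150 bp (strict). The 0.6 difference is interpreted in log2
intensity units, since the tracks are log2 scale throughout. Replicates are
averaged per probe *before* binning; when all replicates share the same
probe set (as array replicates do) this equals binning each replicate and
averaging bins.

Bins with no probes are *missing*, never imputed; a missing bin cannot count
as above threshold. A feature is excluded when (in order of precedence) its
downstream neighbor is closer than the exclusion distance, or so many
downstream bins are missing that the 4-of-6 requirement is unreachable
(e.g. windows truncated at a chromosome end). Class summaries report both
the annotated and the tested denominator so either convention for "fraction
with readthrough" can be computed.

Metagene profiles are unweighted means across features of per-feature bin
means, with missing bins dropped per offset and the number of contributing
features reported. The mutant-minus-wildtype metagene is the difference of
the two condition metagenes.

## Segmentation

The signal model is piecewise-constant with homoscedastic Gaussian noise.
For fixed k, breakpoints minimizing the within-segment sum of squares are
found by exact dynamic programming over segment suffixes (O(k·n²),
vectorized); ties resolve to the lexicographically smallest breakpoint
vector (backtracking from the left with a 1e−9 relative cost tolerance).
k is selected by BIC = −2 log L + p·log n with p = 2k, counting k means,
k−1 breakpoints and one pooled variance; p = k is available via
`params_per_segment=1`. The pooled MLE variance is floored at 1e−12 so that
noiseless step signals (zero residual) stay well defined; on constant input
every k ties and k = 1 wins. Genomic breakpoint coordinates are midpoints
between the flanking probe centers. The default cap k_max = n_probes/50
(floor 1) keeps the search proportional to region size; pass `k_max`
explicitly when a region is known to contain dense structure.

## Expression signatures

The fold-change of mutant m at gene g is
M_g = mean(replicates of m) − mean(all wildtype pool samples), on log2
ratios against a common reference. The per-gene significance stand-in is a
two-sided pooled-variance Student t-test of the mutant replicates against
the wildtype pool: under the shared-error-variance assumption the test is
exactly calibrated, which matters because the filter is applied at raw
p < 0.05 (Welch's form is available via `test="welch"`, but with 4
replicates against a pool of 20 it runs measurably liberal). This is a
simple stand-in for a large reference-pool error model, not a
reimplementation of one; absolute p-values on real arrays should be treated
accordingly. The filter keeps genes with p < 0.05 **and** |M| > log2 1.7 ≈
0.7655, two-sided.

Clustering uses distance 1 − cos(a, b) over the union of significant genes
(a gene missing from a signature contributes 0), agglomerated with average
linkage by default (complete/single configurable); merge ties follow input
order, so results are deterministic. Trees are exportable as Newick with
branch lengths from merge heights. Gene-set enrichment is the upper-tail
hypergeometric probability P[X ≥ k] with population = universe (default:
all genes on the matrix), successes = category, draws = hit set.

## Synthetic data: what it emulates, and what it does not

The generator emulates a strand-specific tiling experiment on a compact
genome: non-overlapping same-strand features of four classes with
class-dependent length ranges, probes every 8 bp on both strands (the
spacing of the whole-genome yeast tiling design this layout follows),
class-dependent baseline expression over feature bodies, and — for planted
features — mutant-specific signal Δ·exp(−d/τ) for d ∈ [0, extent) past the
3′ end (defaults Δ = 1.0 log2, extent 600 bp, decay τ = 500 bp; τ = None
gives a flat extension). Noise has a per-probe affinity offset shared by
all samples (SD 0.25), which cancels exactly in mutant−wildtype differences
like probe-sequence bias on a real array, plus i.i.d. per-probe per-sample
noise (SD 0.3); two replicates per condition. Planted readthrough fractions
default to 32/77 for snoRNAs and 2.8% for ORFs — the genome-wide rates
reported for a Ser2-CTD-kinase deletion — and 30% for CUTs/SUTs, where only
qualitative prevalence ("several sites") is known.

Close-neighbor placement is explicit, not emergent: exactly
round(fraction·count) features per class get a downstream gap drawn from
[20, 149] bp (default fraction 0.1), everything else from [300, 800] bp, so
exclusion-rule tests are deterministic. Gap and placement bookkeeping is
per strand lane, so each feature's neighbor distance is exactly its own
drawn gap.

Expression matrices plant overlapping gene modules (default four modules of
50 genes, effects ±3 log2, with one hub mutant in every module and a
quadruplicate-replicate design against a 20-sample wildtype pool — a
deliberately scaled-down pool; the reference design used two orders of
magnitude more wildtype cultures). Noise is i.i.d. Normal(0, 0.2).

Not modeled: probe-sequence thermodynamics, dye bias, spatial artifacts,
raw-intensity scale (everything is log2 from the start), cross-replicate
probe-set differences, spliced features, and any correlation structure
between the tiling and expression simulations. Passing tests on this
generator therefore demonstrate the correctness of the arithmetic and the
rule logic, and the caller's operating characteristics under idealized
Gaussian noise — not performance on real hybridization data, where
normalization quality dominates. The published normalization/dye-bias
pipeline for real arrays is out of scope; `normalize_tracks` offers global
per-sample median centering as a documented, deliberately simple stand-in.

## Problem sizes and numerical choices

Test and acceptance runs use compact genomes (1–2 chromosomes of 60–200 kb,
50–300 features) chosen so the full study — generation, calling, metagene,
segmentation, clustering — completes in seconds while keeping ≥3 probes per
25 bp bin and realistic feature/gap geometry. The noiseless-recovery check
uses a flat 300 bp extension: at least twice the scoring window but below
the minimum intergenic gap, so one feature's planted extension cannot reach
the next feature's scoring window (with the default 600 bp flat extent that
contamination is real signal, not a caller error). Determinism: every
stochastic routine takes a `numpy.random.default_rng(seed)` stream consumed
in a fixed documented order; identical (config, seed) gives byte-identical
outputs.

## Known limitations

- The readthrough rule is a fixed-threshold classifier; no per-site p-value
  or readthrough-extent estimate is produced.
- The BIC variant (p = 2k, pooled variance) is a documented choice; other
  segmentation penalties will move boundaries on noisy data.
- The significance stand-in ignores the heavy-tailed, intensity-dependent
  error structure of real two-channel arrays.
- Features are single intervals; spliced or overlapping-isoform annotation
  is not resolved.
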