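# Methods

## Digestion model

A restriction enzyme is a name plus an IUPAC recognition sequence over
`ACGTRYSWKMBDHVN`. Matching expands each code to its base set; an `N` *in
the substrate* matches nothing, so ambiguous bases and assembly gaps are
never part of a recognition site. Non-palindromic patterns are additionally
scanned in the reverse-complement orientation with hits reported in forward
coordinates; the six shipped enzymes are all self-reverse-complementary, so
for them a single-strand scan is complete (this is asserted by a property
test).

Digestion is modeled at the string level, not at catalytic cut offsets. The
default `site_removal` mode excises every retained site occurrence and
reports the maximal runs between excisions as fragments; the lengths of
these runs represent the product sizes. This convention slightly shortens
each fragment by the flanking half-sites (5–7 bp per cut) but is simple,
exactly mass-accounted (`Σ fragments + Σ retained sites = |sequence|`), and
is the convention under which the package's enrichment predictions are
defined. A `site_retained` mode (cut at each retained site's start,
every base conserved) is available for comparisons that need physical mass
balance.

**Multi-enzyme resolution.** With several enzymes, and with degenerate
patterns generally, candidate sites can overlap. All candidates from all
enzymes are pooled and resolved jointly by greedy left-most selection; ties
at an equal start position go to the longer recognition sequence, then to
the lexicographically smaller enzyme name. Joint resolution makes the result
independent of the order enzymes are listed, which sequential per-enzyme
substitution would not be. The two schemes differ only in rare
overlapping-site configurations.

**Assembly gaps.** Runs of `N` at least as long as the plan's shortest
recognition sequence are treated as hard fragment boundaries in both modes,
so gaps cannot inflate predicted fragment lengths. Shorter `N` runs (isolated
ambiguous bases) remain inside fragments; they cannot match any site either
way. Soft-masked input is uppercased before matching: repeat masking must
not alter digestion.

## Enrichment prediction

The genome is partitioned into target regions (by default the
`cen_region`-labeled intervals) and their per-chromosome complement, and the
two partitions are digested as separate substrates; sites spanning a
partition boundary never cut. This *per-region* mode treats the annotation
boundary as exact. A `whole_chromosome` mode digests chromosomes intact and
labels each fragment target when ≥ 50 % of its length overlaps target
regions; it models boundary-spanning fragments at the cost of majority-vote
label noise. Per-region is the default because the enrichment quantities are
defined with respect to the annotation.

Fragments are binned by length into half-open bins (default 5-kb steps to
55 kb, then one open-ended high-molecular-weight bin; the top edge matches
the length scale at which intact satellite arrays separate cleanly from
digested background). Per bin the table reports target/total fragment
counts and base-pairs, the two percentages, and `fold_bp = pct_bp_target /
baseline_pct`, where the baseline is the undigested genome's target bp
percentage. An empty target set gives baseline 0 and folds reported as NaN
(absent), never infinity. Percentages pooled over any set of bins are
bp-weighted, so the bp-weighted mean of the per-bin percentages equals the
overall post-digestion percentage (asserted by a test).

**Screening.** `screen_combinations` evaluates every combination of a panel
up to a maximum size. Candidate site positions are computed once per enzyme
per substrate and only the greedy merge is redone per combination, so the
cost is one scan per enzyme plus an O(sites) sweep per combination. The
default objective is the maximum per-bin `fold_bp` over bins with lower edge
≥ 15 kb — the length range a high-molecular-weight selection keeps; a pooled
variant (`agg_fold@<cutoff>`) and a top-bin-percentage objective are
provided, and any callable on the enrichment table is accepted. On small
synthetic genomes whose background is fully shredded, many combinations
saturate at the ceiling `1/f`; ties are broken toward smaller combinations,
then lexicographic names, so an enzyme that contributes nothing never
displaces a smaller equivalent combination. An optional pruning floor drops
enzymes whose solo digestion already pushes the aggregate target percentage
below a threshold (an enzyme that shreds the target cannot be rescued by
partners).

## Sequencing-based quantification

These operations consume reads and count tables produced by external
pipelines; no alignment is performed here.

- **k-mer read classification.** A read is satellite-positive when at least
  `min_hits = 2` of its k-mer windows (k = 18 by default) are members of a
  canonical k-mer set (lexicographic minimum of k-mer and reverse
  complement, so read orientation is irrelevant). Occurrences are counted,
  not distinct k-mers — in tandem-repeat DNA a repeated k-mer is informative
  — with a `distinct` flag for the stricter reading. Windows containing `N`
  never match; reads shorter than k count in the total but cannot be
  positive. The set can be loaded from a plain-text list or derived from a
  monomer (virtually doubled, so junction-spanning k-mers of a head-to-tail
  array are included).
- **Profiles and domains.** Binned counts (2-kb grid by default) from sample
  and control are scaled to a common total (the mean of the two totals) and
  compared as `log2((s·S + p)/(r·R + p))` with pseudocount `p = 1` scaled
  count; a bin absent from one track counts as zero there, and a bin empty
  in both gives exactly 0. Enrichment domains are maximal runs of bins with
  fold strictly above 5; by default no sub-threshold gaps are bridged and
  single bins qualify (`max_gap_bins = 0`, `min_bins = 1` — the strict
  reading of the fold rule), both configurable. Gaps are measured on the
  genomic grid, so missing bins break runs consistently.
- **Residual uncut sites.** Site occurrences in reads are counted with
  overlapping windows allowed and no greedy resolution — reads are
  observations of the substrate, not substrates — in both orientations,
  deduplicated in forward coordinates. The statistic is the percentage of
  sample occurrences relative to a depth-matched undigested control, per
  enzyme and pooled; zero control occurrences make the ratio undefined and
  it is reported as absent.
- **Length proxy.** Per-region percent variation `(A/B − 1)·100` of
  depth-normalized read counts, the standard read-count proxy for satellite
  array length; undefined (absent) where the denominator is zero.

## Methylation comparison

Methylation frequency of a CpG site is `100 · n_meth / n_valid` percent,
where `n_valid` counts reads with any valid call at the site (reads without
a call are excluded upstream) — undefined when `n_valid = 0`.

The change classifier joins two site tables on (chrom, pos), keeping only
sites called in both. Filters and bands are applied as strict inequalities
exactly as stated: a site enters the comparison only when its WT frequency
is > 40 % and its coverage is > 10 in *both* samples (coverage exactly 10 is
excluded); the difference KO − WT in percentage points is `increased` when
> +10, `decreased` when < −10, `unchanged` otherwise — the boundary values
±10 are unchanged. Every joined site receives exactly one of the four
classes and the three change-class proportions are reported among
non-excluded sites. Frequencies are carried as percentages throughout so the
±10 arithmetic operates on percentage points, not ratios.

Family aggregation assigns sites to repeat families by position lookup in
the region annotation and reports the unweighted mean site frequency per
family plus an overall mean; sites outside all annotated regions fall under
`other`. A family-level knockout effect is summarized as the *relative* drop
of the family mean, `1 − mean_KO / mean_WT` — the alternative
percentage-point reading is not used, because the headline effects this
package is designed to recover (~73 % at HSATII vs. ~9.8 % at α-satellite)
are only mutually consistent with family baselines on the relative scale.

**Dip detection.** Hypomethylated subdomains (dip regions) are found by
tiling the track into fixed windows (default 5 kb), averaging site
frequencies per informative window, and reporting maximal runs of
below-threshold windows spanning at least `min_len_bp`, flanked on both
sides by an at-or-above-threshold informative window. The flank requirement
means a uniformly low track yields no dip — a dip is defined relative to its
surroundings. This detector is a convenience for synthetic and enriched
tracks, not a re-implementation of any published CDR caller.

## Synthetic data

The toy genome emulates the features that make the enrichment strategy
work, and only those: a random AT-rich (GC = 0.35) monomer of 171 bp is
rejection-sampled and point-repaired until its *doubled* form contains no
forbidden recognition site (so arrays are site-free across junctions),
repeated into HOR units (default 4 monomers) and arrays (default 50 units =
34,200 bp), and embedded in background whose incidental forbidden sites are
scrubbed and which then receives exact recognition sequences at a
controllable spacing (default 500 bp, jittered ±20 %). Injected sites are
exact instances rather than emergent from base composition, which decouples
expected fragment sizes from background statistics. The default layout — one
34,200-bp array in a 342,000-bp chromosome — has target fraction exactly
0.10, so designed-recovery tests have integer expectations (top-bin purity
100 %, pooled fold 10).

Reads are drawn from the fragment pool passing a size cutoff, uniformly per
base (fragment chosen proportional to length, start uniform), half on the
reverse strand, error-free by default (an optional uniform substitution rate
exists for robustness checks). Methylation tables place sites uniformly in
per-family regions; per-site WT levels are beta-distributed around the
family mean (concentration 30, giving realistic site-to-site spread), KO
levels are the WT level scaled by `1 − relative_drop`, and call counts are
binomial at Poisson coverage (mean 30, floored at 1). Default family
effects: HSATII mean 70 % with relative drop 0.73; α-satellite mean 60 %
with relative drop 0.098.

What the generator does **not** emulate: sequence divergence structure of
real monomeric/divergent α-satellite beyond a uniform substitution option,
CpG-methylation sensitivity of enzymes, partial digestion, nanopore error
and signal models, chromosome-scale genome organization, and mapping
artifacts. Passing tests therefore demonstrate correctness of the counting,
prediction and classification rules under their stated models — not that a
particular enzyme combination achieves a particular enrichment on a real
genome, which depends entirely on the real site distribution and annotation.

## Numerical and design notes

- Coordinates are 0-based half-open everywhere (BED convention).
- Digestion plans require at least one enzyme; the "no digestion" control is
  expressed with an enzyme that has no sites in the substrate, which is
  operationally identical (one fragment per partition, aggregate fold 1).
- Region filters drop intervals shorter than `min_length` *before* merging
  same-label overlaps, matching the order of filtering an annotation by
  array length and then digesting what remains.
- The greedy monotonicity heuristic — adding an enzyme never lengthens any
  fragment — holds whenever new sites do not overlap previously retained
  ones; with overlapping candidates the joint greedy re-resolution can in
  principle swap a retained site for an earlier-starting one. The property
  is asserted on designed genomes with well-separated sites, where it is
  exact.
- All generator randomness flows through `numpy.random.default_rng(seed)`;
  every simulation function takes an explicit seed and is reproducible
  bit-for-bit.
- Tests use problem sizes (a 342-kb toy chromosome, 10,000 reads, 5,000 CpG
  sites) at which every stochastic assertion has comfortable margins under
  its stated confidence bound while the whole suite runs in seconds.

## Known limitations

- Site-removal semantics under-count fragment lengths by the excised site
  bases; for the ≥ 5-kb length scales of interest the bias is negligible,
  but single-fragment comparisons at sub-kb scales should use
  `site_retained`.
- The panel screen is exhaustive over combinations (binomial growth); it is
  intended for panels of tens of enzymes with small `max_size`, with the
  pruning floor as the lever for larger panels.
- `aggregate_by_family` weights sites equally; region-weighted averages are
  not implemented.
- The enrichment predictor assumes complete digestion and loss-free size
  selection; observed enrichments in real experiments are bounded by, and
  generally below, the prediction.
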