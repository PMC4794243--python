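# Methods

## Signal model

The pipeline treats a mononucleosome ChIP-seq experiment as a pair of
fragment sets (ChIP, input) on a common genome. Fragments are genomic
intervals; per-base occupancy is the number of fragments covering a base.
The analysis chain is:

1. **Filtering.** Keep properly paired fragments with mapping score ≥ 30 and
   insert length in the closed interval [50, 240] bp. The bounds are read as
   inclusive; both are configurable (`FragmentFilterSpec`).
2. **Background subtraction.** The input track is depth-scaled to the ChIP's
   total fragment-base count (scaling by fragment-bases rather than fragment
   count makes the subtraction robust to insert-length differences between
   libraries), subtracted element-wise, and clamped at zero. Clamping is
   deliberate: downstream thresholding assumes non-negative enrichment.
3. **Centromere normalization.** The subtracted track is multiplied by a
   single factor so the mean signal over all centromeric bases equals a
   reference level (default 10 000, an arbitrary but fixed scale chosen so
   normalized tracks are comparable across strains). The centromere carries
   a CENP-A nucleosome throughout the cell cycle, which is what makes it a
   valid cross-strain yardstick. The operation is idempotent and errors on
   zero centromeric coverage (a failed ChIP). Among the defensible
   arithmetic conventions (pooled mean over all centromeric bases, mean of
   per-centromere means, summit coverage) the pooled mean is used; for
   near-equal-length point centromeres the alternatives differ negligibly.
4. **Masking.** rDNA-repeat intervals are set to zero before peak calling;
   the repeat's copy number makes single-copy quantification meaningless
   there. Genome-wide averages exclude masked bases from the denominator.
5. **Threshold and peak calling.** The threshold is the minimum over
   centromeres of the mean normalized coverage across that centromere's
   bases, computed on a designated reference strain (the endogenous-level
   tagged strain). Peaks are maximal runs of bases *strictly* above the
   threshold on the masked, unsmoothed track; runs separated by gaps ≤
   `merge_gap` (default 0) are merged and a minimum width (default 0) may
   be applied. Peak center is floor((start + end − 1)/2); score is the run
   maximum. Raising the threshold never increases total peak length and
   every higher-threshold peak nests inside a lower-threshold peak, but the
   peak *count* is not monotone — a bimodal run splits once the threshold
   passes its saddle. Smoothing (centered moving average, odd window,
   default 75 bp, edge-truncated) exists for exported browser tracks only
   and never feeds peak calling.

## Region assignment

Every base receives exactly one label with fixed priority
centromere > pericentromere > telomere > origin > gene > intergenic.
Pericentromeres are derived: each centromere extended by a configurable
flank (default 20 kb, matching the cohesin-enriched domain; the literature
supports 20–50 kb) on both sides, clipped to the chromosome, minus the
centromere itself. Telomeres are taken from the annotation verbatim rather
than inferred from chromosome ends, and genes are labeled over their full
TSS→TTS transcript extent. Peaks are assigned through their single center
base so each peak is counted once even when it straddles a boundary.

Gene hit tables use flank windows of 500 bp upstream of the TSS (promoter)
or downstream of the TTS (3′ end) in transcription orientation — for a '−'
strand gene "upstream" is toward larger coordinates — clipped at chromosome
edges and *not* truncated at neighboring genes (no such rule is defined for
the underlying convention). A gene is hit when ≥ 1 peak center falls in the
window; an any-overlap mode is available behind a flag. Interval-overlap
fractions (CLR/LCNCR sets, H2A.Z nucleosomes) use full-interval overlap
(≥ 1 shared base), not centers.

## Metaprofiles

Mean signal in 10 bp bins covering [−500, +500) around oriented anchors,
bins labeled by their start coordinate; 100 bins, no center bin. Windows are
reversed for '−' anchors so upstream is always negative x. Anchors whose
window leaves the chromosome are dropped (and counted) rather than padded.
The profile is the unweighted mean over anchors — genes are weighted
equally, not by coverage. Grouping schemes: expression quartiles (rank-based
with stable tie-breaking), promoter-NDR presence, NDR length bins (default a
single edge at 65 bp, the length above which enrichment concentrates; the
edges are configurable since finer binnings are equally defensible),
transcription direction of the adjacent intergenic region, and DE class.
Interval anchors (NDR, origin, centromere) use midpoints with '+'
orientation.

A note on direction classes under reflection: mirroring coordinates *and*
flipping strands is a rigid motion, so tandem/convergent/divergent are all
preserved; mirroring coordinates alone swaps convergent and divergent while
fixing tandem. Both identities are covered by tests.

## Overlap statistics

The gene-list overlap test is the upper-tail hypergeometric probability
P(X ≥ k) with k = |A ∩ B|, |A| and |B| the list sizes and N the shared
universe (the full set of genes tested for differential expression).
"At least the observed overlap" is the default tail; the strict variant
P(X > k) is available behind a flag. Computation goes through
`scipy.stats.hypergeom.sf`, which is numerically safe at N in the
thousands; tests validate it against exhaustive enumeration of all draws
for small universes and against the complement identity
P(X ≥ k) = 1 − P(X ≤ k−1) to 1e−12.

## Synthetic data generator

The generator emulates the features the pipeline is sensitive to, on a
desk-scale genome (default 2 chromosomes × 100 kb, 200 000 fragments per
sample; these sizes keep a full four-strain experiment in a few seconds
while leaving ≥ 50 planted ectopic nucleosomes and ≥ 800 baseline
nucleosomes for rate estimates):

* **Layout.** Telomeres (500 bp) at both ends; one 120 bp AT-rich point
  centromere per chromosome (AT fraction 0.9 vs 0.6 background); gene units
  of 300 bp promoter + 1500 bp body tiling the remainder with random
  strand; two origins per chromosome; one 2 kb rDNA-like interval whose
  lattice nucleosomes carry a copy-number weight (default 20) in *both*
  samples plus an extra ChIP multiplier (default 3) so that unmasked rDNA
  would produce a spurious peak — which is what makes masking testable. The
  annotated rDNA mask is padded by the maximum fragment length because
  fragments from edge repeat nucleosomes spill coverage past the repeat
  boundary.
* **Nucleosomes.** A 165 bp-repeat lattice fills gene units. 90 % of
  promoters carry an NDR: the +1 nucleosome center sits at TSS+5 and the −1
  center at +1 − (147 + L) where the NDR length L ~ U[48, 58] (the field
  supports lengths up to ~557 bp; the distribution is configurable). The
  mean −1 position is therefore ≈ TSS−195, i.e. the −1 and +1 apexes of a
  TSS metaprofile fall in the bins containing −200 and 0. The +5 offset
  places the apex mid-bin; a hump centered exactly on a bin boundary would
  make the argmax bin ambiguous under bin-start labeling.
* **Fragments.** Lengths are truncated-normal (mean 150, sd 25, bounded to
  [50, 240]) — every simulated fragment passes the mononucleosome filter —
  and midpoints jitter normally (sd 25 bp) around nucleosome centers,
  matching the positional smear of MNase data; tighter jitter produces
  flat-topped coverage humps whose apex bin is tie-broken by noise.
  Input sampling is proportional to lattice copy weight; ChIP sampling
  additionally weights each nucleosome by its planted multiplier.
* **Strain presets.** The centromeric nucleosome's ChIP multiplier is
  deliberately modest (10×): *in vivo* the centromere is under-recovered by
  MNase (kinetochore binding reduces its solubility), which is exactly why
  ectopic loci can exceed a centromere-derived threshold. Ectopic −1/+1
  multipliers and the fraction of affected promoters scale across presets —
  WT (none), `psh1` (12× at 3 % of NDR promoters), `OE` (15× at 35 %),
  `psh1_OE` (20× at 100 %) — reproducing the strict peak-count ordering of
  the four strains as a structural property. Under the sampling model the
  normalized ectopic level is ≈ reference × (m−1)/(c−1) for ectopic
  multiplier m and centromeric multiplier c, so these presets clear the
  threshold with 1.5–2.5× margin while baseline nucleosomes subtract to ≈ 0.
* **Determinism.** Every stochastic draw flows from `SimulationConfig.seed`
  through fixed, purpose-keyed `SeedSequence` streams; the genome-layout
  stream never consumes preset-dependent draws, so all presets share a
  byte-identical genome at a given seed.
* **DE lists.** Two gene lists with an exactly planted intersection size
  over a supplied universe, for end-to-end checks of the hypergeometric
  machinery.

**What the generator does not model** — and hence what passing tests do not
show about real data: sequencing error and base quality (fragments are
emitted as intervals, not reads; alignment is upstream of this package),
GC/amplification bias, nucleosome phasing decay with distance from the +1,
fragment-length dependence on protein occupancy, chromosomal copy-number
variation beyond the single rDNA block, and biological replicate
variability. Threshold and recovery behavior on real libraries will also
depend on the unspecified smoothing of the upstream coverage tool being
emulated; peaks here are intentionally called on unsmoothed signal.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open internally and in BED/BEDPE/bedGraph;
GFF3 converts at the boundary (1-based closed); fixed-step WIG export
averages each 10 bp step. Empty fragment sets yield empty (not erroneous)
outputs; empty peak sets give 0.0 overlap fractions; an empty region set or
an empty genome is an error. AT% excludes N bases from numerator and
denominator (an all-N span is NaN). Subtraction requires two raw-stage
tracks; normalization and threshold computation require ≥ 1 centromere with
positive coverage; overlapping centromeres on one chromosome are rejected
because they would make the normalization reference ambiguous. Quartile
assignment uses rank with first-occurrence tie-breaking so it is stable
under gene order. Division in profile comparison propagates inf/NaN rather
than erroring.
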