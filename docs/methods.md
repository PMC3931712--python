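# Methods

This note documents the models implemented in `epimotif`, the parameter
choices that matter, what the synthetic data does and does not emulate, and
the numerical conventions a user relying on the outputs should know.

## Coordinates and region model

All internal coordinates are 0-based, half-open `[start, end)`; GFF input
(1-based inclusive) is converted on read, BED input is used as-is.
Chromosomes are partitioned into non-overlapping fixed-width bins
(default 1000 bp); a trailing partial bin is dropped rather than kept, so
every bin has identical width and occupancy counts remain comparable across
bins.  The center of an interval is `start + floor(len/2)` — the
left-of-middle base for even lengths, a convention fixed purely for
determinism.  A test bin is labeled positive when it contains the center of
a reported binding site; with half-open bins a center falling exactly on a
bin boundary belongs to the right-hand bin.

## Position weight matrix

Given N aligned, equal-length binding-site sequences and zero-order
background frequencies q_b, counts receive background-proportional
pseudocounts with total mass P = √N and per-base share p_b = P·q_b:

    f_{b,i} = (c_{b,i} + p_b) / (N + P),      m_{b,i} = log2(f_{b,i} / q_b).

The √N total keeps the prior's weight growing slower than the data, and
distributing it as q_b is consistent with the zero-order background model.
Both are configurable (`pseudocount_total`).  Raw window scores Σᵢ m[wᵢ, i]
are mapped to the relative unit scale (raw − s_min)/(s_max − s_min), where
s_min and s_max are the sums of the per-column minimum and maximum matrix
entries.  The relative score is invariant to the logarithm base (a base
change rescales all entries by one positive constant), which the tests
assert; log2 is used by convention.

Interval scoring slides the matrix over every offset of the bin on the
forward strand and, via the complemented-and-reversed matrix, over the
reverse strand, and takes the maximum relative score.  Windows containing
non-ACGT characters are skipped rather than scored against background —
inventing scores for assembly gaps would leak the gap structure into the
ranking.  An interval with no scorable window at all is assigned 0 (the
worst relative score) so every bin remains rankable.  When PWMs are built
from genomic coordinates, minus-strand sites are reverse-complemented
before counting.

## Nucleosome features

Both features are computed at an anchor position — a binding-site center at
training time, a bin center at test time.  That asymmetry is deliberate: at
prediction time the true site position inside a bin is unknown, so the bin
center is the only available anchor.

* MNN: `min_c |c − anchor|` over the nucleosome centers of one mark on the
  anchor's chromosome.  Distances are unsigned; an equidistant left/right
  tie is the same value by definition.
* MNO: the number of centers in the closed window
  `[anchor − flank, anchor + flank]` (flank default 1000 bp).  Centers are
  counted, not footprint overlaps — the feature is a discrete nucleosome
  count, and a center-based rule has no partial-overlap ambiguity.

Tracks store per-chromosome sorted, deduplicated center arrays; both
features are binary searches.  A mark with no nucleosome on a chromosome
raises at the feature layer; the pipeline substitutes the chromosome length
as a sentinel distance (the worst plausible value), flags the interval in
the output, and warns — silently fabricating small distances is never
acceptable.

## Positional occupancy profiles

The distribution of nucleosomes around binding sites is summarized as, for
each offset relative to the site centers, the number of nucleosome
footprints covering that offset divided by the number of sites.  A
nucleosome occupies ±15 bp around its center (a 31-bp plotted footprint);
with a ±1000 bp window the offsets therefore span −1015..+1015 (2031
values).  No smoothing is applied; the ratio is raw.  Offsets with
|offset| ≤ 1000 receive contributions from every nucleosome whose footprint
reaches them; the outermost 15 bp on each side are partially eroded by the
window cut, so shape statistics (peak finding, flatness) are evaluated on
|offset| ≤ 1000.

## Logistic regression classifier

Unregularized binary cross-entropy (an optional L2 penalty, default off, is
available for ill-conditioned mark combinations; the intercept is never
penalized).  The cost uses `ln(1+e^z) = logaddexp(0, z)`, so it is finite
for arbitrarily large |z|, and the analytic gradient `(1/m)Xᵀ(h−y)` is
verified against central finite differences.  Features are z-scored with
training-set statistics that are stored on the model and applied
identically at prediction; raw genomic distances reach 10⁶–10⁸ bp and would
make the optimization badly conditioned otherwise.  Zero-variance features
are dropped with a warning.  Optimization is BFGS from θ = 0 to gradient
norm 1e−6 or 500 iterations; the cost is convex, so the optimum is
initialization-independent (tested, not assumed).  Models serialize to JSON
and reproduce probabilities bit-identically after reload.

## Training and test sets

Training examples anchor at binding-site centers on the training chromosome
(positives) and at exactly two uniformly sampled positions per positive in
non-gapped sequence of the same chromosome (negatives), drawn with a seeded
generator.  Non-gapped regions are maximal N-free runs of at least 1 kb, so
a full flanking window exists around any sampled anchor; sampling is
uniform over their union, with no exclusion zone around true sites (an
unknown fraction of negatives may fall near real sites; at genomic density
this contaminates the negative class negligibly).  Test examples are all
1-kb bins of the remaining chromosomes.

The fused region score is the product of the classifier probability and the
relative matrix score.  Both factors live in [0, 1], the product does too,
and it preserves ranking dominance: among bins with equal chromatin
probability, sequence decides, and vice versa.  A weighted geometric mean
(`combine: loglinear`) is available as an alternative; since AUC is
invariant under monotone transforms, the two differ only in how they trade
off the factors, not in either factor's own ranking.  Because the chromatin
features capture a general accessibility signal rather than one factor's
preference, a classifier trained on one factor's sites can be transferred:
its probabilities are multiplied with a different factor's PWM scores to
produce predictions specific to that factor (`transfer_predict`).

## Evaluation

ROC curves are built by a descending-score threshold sweep with tied scores
grouped at a single step; AUC is the trapezoidal integral, equal to the
Mann–Whitney pair statistic with half-credit for ties (asserted against a
brute-force pair count and against scikit-learn).  Multi-chromosome results
are reported both pooled (all bins in one ranking — the primary number, as
it corresponds to a single genome-wide prediction list) and macro-averaged
(unweighted mean of per-chromosome AUCs).  No multiple-testing machinery is
applied; the method is evaluated on raw rankings.

## Synthetic data

The generator emulates the three real inputs — genome FASTA, binding-site
GFF, per-mark nucleosome tracks — with the statistical structure the method
assumes:

* **Genome**: i.i.d. bases at a configurable GC content (default 0.5), with
  planted assembly-gap N-runs (default: one run of 1% of the chromosome at
  60% of its length).
* **Sites**: `n_sites` (default 500) per chromosome, non-overlapping,
  at least 1 kb apart, ≥2 kb from chromosome ends and gap edges.  Each site
  is an instance of a 10-bp GC-box-like consensus (GGGGCGGGGC) with a 0.1
  per-position mutation rate, planted on a random strand.  The 1-kb minimum
  separation means at most one site per bin-sized stretch and keeps each
  site's local chromatin geometry unentangled from its neighbors'.
* **Active marks** (defaults: H3K4me3, H2A.Z): per site, 8 nucleosome
  centers drawn from an equal mixture of Gaussians at offsets ±150 bp
  (sd 50 bp), rejected from the ±40 bp nucleosome-free zone, plus a uniform
  background of 0.2 centers/kb; background centers are also excluded from
  every site's free zone.
* **Repressive marks** (defaults: H3K27me3, H3K9me3): uniform background
  only, 10 centers/kb.  This density is deliberately high: the profile
  flatness statistic has relative sampling error
  ~ 1/√(n_sites·rate·footprint) per offset, and at desk-scale site counts a
  sparser track would look noisy rather than flat.  Real data achieves flat
  repressive profiles with orders of magnitude more sites instead.
* **Moderate marks**: active geometry at a quarter of the per-site cluster
  size (not part of the default mark set).

Everything is a pure function of the seed; regenerating with the same seed
reproduces identical files, and all emitted files parse through the
package's own readers.

What the generator does **not** emulate: read-level ChIP-seq artifacts
(duplicates, mappability, tag-shift), nucleosome-calling noise, sequence
composition structure (CpG islands, repeats), correlated marks on shared
nucleosomes, and binding-site clustering.  Consequently the synthetic AUCs
(matrix ≈ 0.90, chromatin classifier ≈ 0.99, fused ≈ 0.994 at defaults)
characterize the pipeline's correctness and the qualitative ordering of the
scores — chromatin features dominate, fusion beats sequence alone — not the
accuracy attainable on real genomes.

## Numerical conventions and degenerate inputs

Relative scores are clipped to [0, 1] only against floating-point drift; a
degenerate matrix (s_min = s_max) is rejected at construction.  Duplicate
nucleosome centers collapse to one entry (the track is a position set, not
coverage).  Score tables are written with 6-decimal floats in (chrom,
start) order so reruns are byte-identical and diff-able; for the same
reason no timestamps appear in outputs — provenance (seed, config and input
checksums) lives in `run_log.json`.  Configuration files reject unknown
keys.

## Known limitations

* Scanning is desk-scale: pure-NumPy window scoring is comfortable up to
  tens of megabases, not for whole mammalian genomes.
* Heterogeneous-length binding sites are rejected at PWM construction; the
  package does not align sites.
* The negative-control sampler does not avoid true sites (see above).
* The classifier is intentionally minimal — no cross-validation,
  regularization paths or alternative models.
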